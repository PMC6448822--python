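import pytest

from regevol import synthetic


@pytest.fixture(scope="session")
def tritici():
    """The preset homoeolog family with programmed +1/+1/-1 promoter TGTC ledger."""
    return synthetic.tritici_family(seed=11)


@pytest.fixture(scope="session")
def protein_family():
    return synthetic.simulate_protein_family(seed=11)
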