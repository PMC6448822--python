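# regevol

Cis-regulatory and protein-motif evolution of *DRO1-like* homoeologs.

Deeper-rooting genes of the *DRO1*/IGT family control root growth angle in
cereals and are negatively regulated by auxin. Hexaploid wheat carries three
homoeologous copies (A, B and D subgenomes) whose root-tip expression
diverges sharply, and a leading explanation is the gain and loss of auxin
response elements (AuxREs) in their promoters and introns since divergence
from the diploid progenitors. `regevol` is a library for making that kind of
comparison reproducible:

- **Promoter/intron motif scanning** of IUPAC-degenerate elements (AuxRE
  `TGTCTC`, core `TGTC`, coupling `ATTTTCTT`, CArG-boxes) under the signed
  ATG-anchored coordinate convention (−1 is the base just upstream of ATG,
  +1 the A of ATG), with region labels from exon structure and composite
  AuxRE + coupling-element detection.
- **Gain/loss ledgers** of per-(motif, region) counts along
  progenitor → descendant lineage edges, with qualitative expression ranks
  joined on.
- **Protein motif analysis** for the IGT family: the G-Φ-L-(A/T)-G-T
  denominator motif, the C-terminal family motif WxxTD, EAR-like C-terminus
  classification (canonical IVLEM/IVLEI, extended KLHTLIPNK, divergent,
  none) and the truncation that abolishes TOPLESS interaction, plus
  conserved domain blocks (I–V) in a protein MSA.
- **Distance phylogenetics**: p-distance / JC69, neighbor joining with
  deterministic tie-breaking, bootstrap supports, newick output, and k-mer
  dotplots for promoter comparison.
- **Quantitative assays**: 2^−ΔΔCt fold expression with multiple reference
  genes (fold = 2^−(mean ΔΔCt), calibrator exactly 1), Miller units
  U = 1000·OD420/(t·V·OD600), Welch t tests, morphometric summaries.
- **Synthetic data with exact ground truth** for every stage: planted
  motifs, programmed gain/loss scenarios, protein families with assigned
  C-termini, alignments evolved down a known tree, Ct tables with programmed
  folds.

The published per-gene AuxRE position lists for 17 *DRO1-like* orthologs,
the three tritici lineage edges and the qualitative expression ranks are
bundled in `regevol.datasets`.

## Worked example

Feed the bundled position lists into the gain/loss ledger
(`examples/02_gain_loss_ledger.py`):

```python
from regevol import datasets
from regevol.gainloss import LineageEdge, LineageMap, build_ledger

tallies = datasets.auxre_tallies()
lineages = LineageMap([LineageEdge(*e) for e in datasets.TRITICI_LINEAGES])
ledger = build_ledger(lineages, tallies)
for e in ledger.entries:
    if e.motif == "TGTC" and e.region == "promoter":
        print(f"{e.parent} -> {e.child}: {e.parent_count} -> {e.child_count} "
              f"({e.delta:+d})")
```

prints

```
TuDRO1 -> TaADRO1: 1 -> 2 (+1)
AsDRO1 -> TaBDRO1: 5 -> 6 (+1)
AtaDRO1 -> TaDDRO1: 4 -> 3 (-1)
```

i.e. the A and B wheat homoeologs each gained one promoter TGTC relative to
their diploid progenitors while the D homoeolog lost one — the count-based
evolutionary ledger behind the expression-divergence argument. The other
scripts under `examples/` demonstrate promoter scanning with composite
elements, protein motif classification and truncation, NJ + bootstrap on a
simulated alignment, and ΔΔCt fold recovery; each prints its numbers with a
line on what they mean.

A thin CLI mirrors the library (`regevol scan | composite | protein-scan |
domains | gainloss | nj | dotplot | expr | miller | simulate | run`); see
`regevol --help`.

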