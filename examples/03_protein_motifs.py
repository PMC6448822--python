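"""IGT-family protein motifs: IGT, WxxTD, EAR-like C-termini, domains I-V.

Simulates a protein family sharing five conserved domains with assigned
C-terminal EAR-like motifs, then classifies each member's extreme C-terminus
and locates the conserved blocks in the (gap-free) family alignment.
"""

from regevol.proteinmotifs import (
    BUILTIN_PATTERNS, classify_cterm_ear, conserved_blocks, scan_protein,
    truncate_cterm,
)
from regevol.synthetic import simulate_protein_family

fam = simulate_protein_family(seed=42)

print("member  len  IGT@  WxxTD@  C-terminal EAR class")
for pid, seq in fam.records:
    igt = scan_protein(seq, BUILTIN_PATTERNS["IGT"])
    wxxtd = scan_protein(seq, BUILTIN_PATTERNS["WxxTD"])
    ear = classify_cterm_ear(seq, protein_id=pid)
    print(f"{pid:<7} {len(seq):<4} {igt[0].start:<5} {wxxtd[0].start:<7} "
          f"{ear.cterm_class} ({ear.matched or '-'})")

pid, seq = fam.records[0]
ear = classify_cterm_ear(seq)
short = truncate_cterm(seq, ear)
print(f"\ntruncating {pid}: {len(seq)} aa -> {len(short)} aa; reclassified as "
      f"{classify_cterm_ear(short).cterm_class!r}")
print("(removing IVLEM/KLHTLIPNK is what abolishes TOPLESS interaction)")

print("\nconserved blocks in the family alignment (threshold 0.7, min 5 cols):")
for b in conserved_blocks(fam.alignment):
    print(f"  domain {b.domain_index:<3} columns {b.msa_column_span[0]:>3}-"
          f"{b.msa_column_span[1]:<3} conservation {b.mean_conservation:.2f}")
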