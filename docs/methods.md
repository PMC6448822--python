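# Methods

`regevol` reimplements, as a tested library, a comparative analysis of
cis-regulatory and protein-motif evolution in *DRO1-like* (DEEPER ROOTING
1-like) homoeologs of hexaploid wheat and their diploid relatives. This note
documents the models, conventions, parameters and limitations.

## Coordinate model

All user-facing positions are signed and anchored at the start codon: the
base immediately 5' of ATG is −1 and positions increase downstream, with no
position 0. The source convention states only that upstream is −1 and
downstream +1; it does not say whether +1 is the A of ATG or the first base
after it. We assign **+1 to the A of ATG** and use that consistently in all
reports (`seqio.to_signed_position`). Internally everything is 0-based
half-open; signed coordinates appear only at I/O boundaries.

A locus is a coding-strand sequence with an ATG anchor and exon intervals
(exon 1 starts at the ATG; the gene model runs ATG → stop with introns).
Promoters are the `min(length, atg_index)` bases immediately upstream of ATG,
2000 bp by default, flagged `truncated` when the locus holds less upstream
sequence. Exon structure comes from a simple TSV (`gene_id, exon_start,
exon_end`, 1-based inclusive); a GFF3 importer normalizes into the same
model. A motif hit is labelled `promoter`, `exon` or `intron` only when it
lies entirely inside one such region; hits crossing the ATG or an
exon/intron junction are labelled `spanning` and excluded from
promoter/intron tallies, since the source reports contain no such hits.

## Motif scanning

Patterns are IUPAC-degenerate DNA strings. Scanning is exact (no mismatch
tolerance, no PWM scoring), reports all overlapping occurrences, and is
forward-strand only by default — the tabulated positions we mirror are
single signed coordinates with no strand column. The reported coordinate
anchors the 5'-most matched base. An `N` in the scanned sequence matches no
pattern base (conservative); an `N` in a pattern matches any base. Built-in
registry: AuxRE `TGTCTC`, AuxRE core `TGTC`, coupling AuxRE-like `ATTTTCTT`,
CArG-box `CCWWWWWWGG` and its N10-like instance `CCAAATATGG`. Overlapping
matches of different patterns (e.g. the TGTC inside every TGTCTC) are
reported independently per pattern.

A **composite element** is a coupling ATTTTCTT whose 3' end lies at most
`window` bp (default 250, configurable — the source says only "in close
vicinity") upstream of an AuxRE 5' start; one coupling hit may pair with
several AuxREs.

## Gain/loss ledger

The ledger compares per-(motif, region) counts between a progenitor gene and
its descendant along user-supplied lineage edges; `delta = child − parent`,
missing keys counting 0. It is purely count-based: no positional orthology
of individual instances is attempted, matching the count-based reasoning of
the source. With the published position lists bundled in
`regevol.datasets`, the promoter-TGTC deltas along the A, B and D lineages
are +1, +1 and −1.

Known inconsistency in the source: its discussion says TaBDRO1 carries
"6+7" TGTCs (promoter+introns) and TaDDRO1 "4+7", but its table prints six
intronic positions for TaBDRO1 and three promoter positions for TaDDRO1.
The table lists are treated as authoritative here; full-region (−2 kb
promoter) counts are reported, with windowed re-analysis left to
configuration.

## Protein motifs and domains

The IGT family motif is G-Φ-L-(A/T)-G-T with Φ = {A,V,L,I,M,F,W,C}; the
EAR-like LxLxL test uses Φ-x-Φ-x-Φ with Φ = {L,I,V,M}. Both hydrophobic
sets are configurable, since the source uses Φ and "LxLxL" without defining
the sets. `WxxTD` is the domain-V family motif. The C-terminal classifier
inspects the last 15 residues (bounding the "extreme C-terminus") with
precedence extended > canonical > divergent: a registry motif carrying the
IPNK suffix (KLHTLIPNK) is *extended*; an LxLxL-type match (IVLEM, IVLEI) is
*canonical*; any other registry motif is *divergent*. KLHTLIPNK does not
satisfy the strict Φ-x-Φ-x-Φ test; it is recognized by name because the
family literature explicitly calls it EAR-like. The registry is a
user-extensible TSV. Truncation removes the motif and everything C-terminal
of it (a 251-aa protein ending IVLEM yields the 246-aa product used in the
interaction assays).

Conserved blocks in a protein MSA: per-column conservation is the frequency
of the modal non-gap residue among non-gap rows, with columns over 50% gaps
scoring 0; maximal runs of at least `min_block_length` (5) columns at or
above `threshold` (0.7) are returned N→C and the first five are labelled
I–V. The pipeline ingests aligned FASTA and does not compute alignments.

## Phylogenetics

Distances are p-distances with pairwise deletion by default (the original
tree-building settings are unreported); JC69 correction
d = −(3/4)·ln(1 − 4p/3) is available by flag and errors at p ≥ 0.75.
Neighbor joining is the standard Saitou–Nei agglomeration on the Q-matrix
with two documented conventions: ties in the Q minimum break to the
lexicographically smallest (i, j) pair, and negative branch-length estimates
are clamped to 0 with a warning. On additive matrices the tree's path
distances reproduce the input exactly. Bootstrap resamples alignment
columns with replacement; the support of each internal bipartition of the
full-data tree is the percentage of replicate trees containing it
(bipartitions are canonicalized leaf sets, so supports are invariant to
taxon order). Tests and examples use 100 replicates; larger replicate
counts are supported but unnecessary for the desk-scale demonstrations.
Exact reproduction of the published 82-taxon tree is out of scope (it needs
external sequence retrieval and the original program's unreported options).

The promoter dotplot reports every exact shared w-mer start pair (default
w = 10) and the fraction of the first sequence covered by at least one
match.

## Quantitative assays

Fold expression uses the 2^-ddCt method with amplification efficiency fixed
at 2 (no standard-curve module is described in the source). Multiple
reference genes are combined by the arithmetic mean of their Cts, which
equals the geometric mean of reference quantities — the source names two
controls (*elf*, *tubulin*) but no combination rule. Per replicate,
ΔCt = Ct_target − mean(Ct_refs); ΔΔCt subtracts the calibrator sample's mean
ΔCt. The reported per-sample fold is 2^(−mean ΔΔCt) — the geometric mean of
per-replicate folds — so the calibrator's fold is exactly 1 by construction;
the error bar is the sd of the per-replicate folds. (An arithmetic mean of
per-replicate folds would exceed 1 for the calibrator whenever replicates
differ, by Jensen's inequality, which is why the geometric form is used.)
Which sample served as calibrator in the source is unstated; all fixtures
designate it explicitly.

Miller units follow U = 1000·OD420/(t[min]·V[ml]·OD600). Group comparisons
default to the Welch unequal-variance t statistic with Welch–Satterthwaite
degrees of freedom (a conservative default; pooled Student is available by
flag). Morphometric tables are summarized as grouped mean, sample sd and n,
with single-value groups reporting sd 0 and n = 1.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions for every test:

- **Regulatory families** (`simulate_regulatory_family`): a 2000 bp
  uniform-composition promoter plus a five-exon/four-intron gene body
  (defaults 300/200/150/100/250 bp exons, 500/400/300/200 bp introns, a
  typical structure for these loci). Motifs are planted at stated signed
  positions; descendants apply programmed gains (overwrite, never insert, so
  coordinates stay comparable — mirroring the count-based gain/loss
  reasoning), losses (single-base disruption at the most-constrained pattern
  position), and point substitutions at 1% per base per edge (realistic for
  homoeolog divergence), masked inside planted motifs. Backgrounds are
  scrubbed of accidental matches of the whole motif set, so scanner recall
  on truth instances is exactly 100% with zero false positives; matches
  fully inside planted spans (the TGTC inside a planted TGTCTC) are recorded
  as derived truth by a generator-internal naive matcher that is independent
  of the production scanner. The `tritici_family` preset programs the
  +1/+1/−1 promoter-TGTC scenario across six edges.
- **Protein families**: members share five verbatim domain blocks separated
  by per-member random linkers and end in an assigned EAR-like motif; all
  members have equal length, so the emitted alignment is gap-free by
  construction. Members assigned "none" draw their tail from
  non-hydrophobic residues so no spurious LxLxL match can arise.
- **Alignments** evolve down a newick tree under Jukes–Cantor (per-site
  change probability (3/4)(1 − e^(−4t/3)) per branch).
- **Ct tables** draw reference Cts around fixed baselines (19 and 21
  cycles), offset the target by −log2(fold), and add Gaussian technical
  noise; with all noise at 0 the programmed folds are recovered exactly.

What passing these tests does *not* show about real data: real promoters
have non-uniform base composition and background motif occurrences (so real
scans have "false positives" relative to any curated list), real homoeologs
diverge by indels as well as substitutions (no indel evolution is
simulated), real alignments contain gaps, and real qPCR has
efficiency != 2 and reference-gene instability beyond the simple shift model
used here.

## Problem sizes and numerical choices

Desk-scale demonstrations use: 200 random 2-kb sequences for the
scanner/oracle agreement; 50 additive matrices for NJ correctness; an
8-taxon, 2000-bp alignment with 100 bootstrap replicates; 100 simulation
seeds for fold recovery at Ct sd 0.15; a 500-point random grid for the
Miller formula. These sizes give stable results (the stochastic quantities
vary by well under their tolerances across seeds) while keeping the whole
suite under a minute.

Degenerate inputs are errors, not silent defaults: empty FASTA, non-IUPAC
characters (named with record and position), loci with no upstream sequence,
mixed-gene hit lists, ragged alignments, pairs with no comparable sites,
saturated p-distances, non-positive Ct values, and degenerate t-test groups.

## Known limitations

- No PWM/TFBS-database scanning (the database-dependent site census of the
  source is out of scope), no ancestral-state reconstruction, no statistical
  test of gain/loss rates, no alignment construction, no ML/Bayesian trees.
- The ledger is count-based; positional orthology of motif instances is a
  documented non-goal.
- Reverse-strand scanning exists behind an option but all bundled reports
  follow the forward-strand convention of the source tables.
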