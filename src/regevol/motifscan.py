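"""Degenerate (IUPAC) DNA motif scanning and Table-1-style reporting.

The scanner finds every — possibly overlapping — occurrence of an IUPAC
pattern on the coding strand, reports the signed ATG-anchored coordinate of
the 5'-most matched base, and labels each hit by the region it falls in
(promoter / exon / intron / spanning).  Built-in patterns cover the auxin
response element (AuxRE) TGTCTC and its core TGTC, the coupling AuxRE-like
octamer ATTTTCTT, and the CArG-box (canonical CCWWWWWWGG plus the N10-like
instance CCAAATATGG).

An ``N`` in the *sequence* never matches any pattern base (conservative); an
``N`` in a *pattern* matches any of A/C/G/T.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values

from . import seqio
from .seqio import INTRON, PROMOTER, LocusRecord, extract_promoter, to_signed_position

#: IUPAC code -> set of concrete bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items() if code != "X"
}


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate DNA pattern (IUPAC codes ACGTRYSWKMBDHVN)."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"pattern {self.name!r} is empty")
        for ch in self.pattern.upper():
            if ch not in IUPAC_SETS:
                raise ValueError(f"pattern {self.name!r}: invalid IUPAC code {ch!r}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)


#: Built-in registry: the motifs the study scans for.
BUILTIN_MOTIFS: dict[str, MotifPattern] = {
    "TGTCTC": MotifPattern("TGTCTC", "TGTCTC"),        # AuxRE
    "TGTC": MotifPattern("TGTC", "TGTC"),              # AuxRE core
    "AuxRE-like": MotifPattern("AuxRE-like", "ATTTTCTT"),  # coupling element
    "CArG-N10": MotifPattern("CArG-N10", "CCAAATATGG"),
    "CArG": MotifPattern("CArG", "CCWWWWWWGG"),
}


def read_motif_tsv(path: str | Path) -> dict[str, MotifPattern]:
    """Load user patterns from a TSV with columns ``name`` and ``pattern``."""
    patterns: dict[str, MotifPattern] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"name", "pattern"}.issubset(reader.fieldnames):
            raise ValueError(f"motif table {path} must have columns name, pattern")
        for row in reader:
            patterns[row["name"]] = MotifPattern(row["name"], row["pattern"])
    if not patterns:
        raise ValueError(f"no motifs in {path}")
    return patterns


@dataclass(frozen=True, order=True)
class MotifHit:
    """One pattern match, anchored at the signed position of its 5'-most base."""

    gene_id: str
    motif_name: str
    position: int  # signed ATG-anchored coordinate
    region: str
    length: int
    matched: str
    strand: str = "+"

    def linear(self) -> int:
        """Collapse the signed coordinate onto a gapless integer axis.

        Signed coordinates skip 0, so upstream values map to themselves and
        downstream values shift by one; differences on this axis are base-pair
        distances.
        """
        return self.position if self.position < 0 else self.position - 1


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    # sequence N is excluded automatically: classes only ever list ACGT subsets
    parts = []
    for ch in pattern:
        bases = sorted(IUPAC_SETS[ch])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("(?=" + "".join(parts) + ")")


def scan_iupac(sequence: str, pattern: MotifPattern | str) -> list[int]:
    """All (possibly overlapping) 0-based start indices where ``pattern`` matches.

    The sequence must be uppercase A/C/G/T/N; ``N`` in the sequence matches
    nothing.  Returned indices are sorted ascending.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern, pattern)
    return [m.start() for m in _pattern_regex(pattern.pattern).finditer(sequence)]


def scan_gene(
    locus: LocusRecord,
    patterns: Iterable[MotifPattern] | None = None,
    promoter_length: int = 2000,
    both_strands: bool = False,
) -> list[MotifHit]:
    """Scan the extracted promoter and the downstream locus for every pattern.

    Hits upstream of the promoter window are discarded; everything else keeps
    the signed coordinate of its 5'-most base and a region label.  Scanning is
    forward (coding) strand only by default; with ``both_strands`` a
    reverse-strand occurrence is reported with the coordinate of its 5'-most
    base on the coding strand and strand "-".  Hits are sorted by coordinate,
    then motif name.
    """
    from Bio.Seq import Seq

    if patterns is None:
        patterns = BUILTIN_MOTIFS.values()
    promoter = extract_promoter(locus, promoter_length)  # propagates "no upstream sequence"
    window_start = locus.atg_index - len(promoter.sequence)
    hits: list[MotifHit] = []

    def collect(pat: MotifPattern, scan_pattern: str, strand: str) -> None:
        for i in scan_iupac(locus.sequence, MotifPattern(pat.name, scan_pattern)):
            if i < window_start:
                continue
            span = (i, i + len(pat))
            hits.append(
                MotifHit(
                    gene_id=locus.id,
                    motif_name=pat.name,
                    position=to_signed_position(i, locus.atg_index),
                    region=seqio.classify_region(span, locus),
                    length=len(pat),
                    matched=locus.sequence[i : i + len(pat)],
                    strand=strand,
                )
            )

    for pat in patterns:
        collect(pat, pat.pattern, "+")
        if both_strands:
            rc = str(Seq(pat.pattern).reverse_complement())
            if rc != pat.pattern:  # palindromes already reported once
                collect(pat, rc, "-")
    hits.sort(key=lambda h: (h.linear(), h.motif_name, h.strand))
    return hits


@dataclass(frozen=True)
class CompositeElement:
    """An AuxRE with a coupling AuxRE-like element a short distance upstream."""

    auxre_hit: MotifHit
    coupling_hit: MotifHit
    gap: int  # bp between coupling 3' end and AuxRE 5' start


def detect_composite(
    hits: Sequence[MotifHit],
    auxre_names: frozenset[str] | set[str] = frozenset({"TGTCTC", "TGTC"}),
    coupling_name: str = "AuxRE-like",
    window: int = 250,
) -> list[CompositeElement]:
    """Pair every coupling-element hit with each AuxRE at most ``window`` bp downstream.

    The coupling element must lie strictly upstream (its 3' end at or before
    the AuxRE 5' start); one coupling hit may pair with several AuxREs.
    """
    genes = {h.gene_id for h in hits}
    if len(genes) > 1:
        raise ValueError(f"hits from multiple genes: {sorted(genes)}")
    couplings = [h for h in hits if h.motif_name == coupling_name]
    auxres = [h for h in hits if h.motif_name in auxre_names]
    composites = []
    for c in couplings:
        c_end = c.linear() + c.length
        for a in auxres:
            gap = a.linear() - c_end
            if 0 <= gap <= window:
                composites.append(CompositeElement(auxre_hit=a, coupling_hit=c, gap=gap))
    composites.sort(key=lambda x: (x.coupling_hit.linear(), x.auxre_hit.linear()))
    return composites


@dataclass
class MotifTally:
    """Per-gene counts and sorted position lists keyed by (motif, region)."""

    gene_id: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    positions: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    def count(self, motif: str, region: str) -> int:
        return self.counts.get((motif, region), 0)


def tally(hits: Sequence[MotifHit], gene_id: str | None = None) -> MotifTally:
    """Aggregate hits of one gene into a :class:`MotifTally`.

    Spanning and exon hits are kept under their own region keys, so promoter
    and intron tallies contain only clean within-region hits.
    """
    genes = {h.gene_id for h in hits}
    if len(genes) > 1:
        raise ValueError(f"hits from multiple genes: {sorted(genes)}")
    if gene_id is None:
        if not genes:
            raise ValueError("empty hit list needs an explicit gene_id")
        gene_id = genes.pop()
    elif genes and genes != {gene_id}:
        raise ValueError(f"hits belong to {genes.pop()}, not {gene_id}")
    result = MotifTally(gene_id=gene_id)
    for h in hits:
        key = (h.motif_name, h.region)
        result.positions.setdefault(key, []).append(h.position)
    for key, pos in result.positions.items():
        pos.sort()
        result.counts[key] = len(pos)
    return result


def tally_from_positions(
    gene_id: str, positions: Mapping[tuple[str, str], Sequence[int]]
) -> MotifTally:
    """Build a tally directly from signed position lists (e.g. a published table)."""
    result = MotifTally(gene_id=gene_id)
    for key, pos in positions.items():
        spos = sorted(int(p) for p in pos)
        result.positions[key] = spos
        result.counts[key] = len(spos)
    return result


_TABLE1_COLUMNS = [
    ("TGTCTC", PROMOTER),
    ("TGTCTC", INTRON),
    ("TGTC", PROMOTER),
    ("TGTC", INTRON),
]


def _format_cell(positions: Sequence[int]) -> str:
    if not positions:
        return "-"
    return ", ".join(f"{p:+d}" if p > 0 else str(p) for p in positions)


def write_table1_report(
    tallies: Sequence[MotifTally],
    path: str | Path,
    columns: Sequence[tuple[str, str]] = tuple(_TABLE1_COLUMNS),
) -> None:
    """Write the per-gene AuxRE position report (Table-1 layout).

    Columns are ``Gene`` plus ``<motif>_<region>`` position lists, comma-joined
    with their signs; an empty cell is rendered "-".
    """
    if not tallies:
        raise ValueError("no tallies to report")
    header = ["Gene"] + [
        f"{motif}_{'promoter' if region == PROMOTER else 'introns'}" for motif, region in columns
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(header)
        for t in tallies:
            row = [t.gene_id]
            for key in columns:
                row.append(_format_cell(t.positions.get(key, [])))
            writer.writerow(row)


def read_table1_report(
    path: str | Path,
    columns: Sequence[tuple[str, str]] = tuple(_TABLE1_COLUMNS),
) -> list[MotifTally]:
    """Parse a Table-1-layout TSV back into tallies (inverse of the writer)."""
    tallies = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[0] != "Gene" or len(header) != len(columns) + 1:
            raise ValueError(f"unexpected report header in {path}: {header}")
        for row in reader:
            positions: dict[tuple[str, str], list[int]] = {}
            for key, cell in zip(columns, row[1:]):
                cell = cell.strip()
                if cell and cell != "-":
                    positions[key] = [int(x.strip()) for x in cell.split(",")]
            tallies.append(tally_from_positions(row[0], positions))
    return tallies
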