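"""IGT-family protein motifs: IGT, WxxTD, EAR-like C-termini, conserved domains.

The IGT family (DRO1, LAZY, NGR, TAC1) is named for the domain-II motif
GPhiL(A/T)GT; WxxTD is the family motif of domain V at the C-terminus.  The
EAR-like repression motif at the extreme C-terminus comes in a canonical
LxLxL-type form (IVLEM, IVLEI) and an extended 9-residue form KLHTLIPNK that
carries the IPNK suffix; removing it abolishes TOPLESS interaction, which is
why truncation is a first-class operation here.

Hydrophobic classes are configurable: Phi in the IGT pattern defaults to
{A,V,L,I,M,F,W,C}; Phi in the EAR LxLxL test defaults to {L,I,V,M}.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

IGT_HYDROPHOBIC = frozenset("AVLIMFWC")
EAR_HYDROPHOBIC = frozenset("LIVM")

CANONICAL = "canonical"
EXTENDED = "extended"
DIVERGENT = "divergent"
NONE = "none"


@dataclass(frozen=True)
class ProteinPattern:
    """Ordered residue classes; ``None`` elements are wildcards (x)."""

    name: str
    elements: tuple[frozenset[str] | None, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError(f"pattern {self.name!r} is empty")
        for el in self.elements:
            if el is not None and (not el or not el <= STANDARD_AA):
                raise ValueError(f"pattern {self.name!r}: invalid residue class {el}")

    def __len__(self) -> int:
        return len(self.elements)

    @classmethod
    def from_string(cls, name: str, spec: str) -> "ProteinPattern":
        """Parse e.g. ``G[AVLIMFWC]L[AT]GT`` or ``WxxTD`` (lowercase x = wildcard)."""
        elements: list[frozenset[str] | None] = []
        i = 0
        while i < len(spec):
            ch = spec[i]
            if ch == "[":
                j = spec.index("]", i)
                elements.append(frozenset(spec[i + 1 : j].upper()))
                i = j + 1
            elif ch == "x":
                elements.append(None)
                i += 1
            else:
                elements.append(frozenset(ch.upper()))
                i += 1
        return cls(name, tuple(elements))


def igt_pattern(hydrophobic: frozenset[str] = IGT_HYDROPHOBIC) -> ProteinPattern:
    """The family-denominator motif G-Phi-L-(A/T)-G-T of domain II."""
    return ProteinPattern(
        "IGT",
        (
            frozenset("G"),
            hydrophobic,
            frozenset("L"),
            frozenset("AT"),
            frozenset("G"),
            frozenset("T"),
        ),
    )


WXXTD_PATTERN = ProteinPattern.from_string("WxxTD", "WxxTD")


def ear_lxlxl_pattern(hydrophobic: frozenset[str] = EAR_HYDROPHOBIC) -> ProteinPattern:
    """The LxLxL-type EAR test: Phi-x-Phi-x-Phi with Phi in {L,I,V,M}."""
    return ProteinPattern("EAR-LxLxL", (hydrophobic, None, hydrophobic, None, hydrophobic))


#: Full canonical EAR consensus (L/F)DLN(L/F)xP, provided for completeness.
EAR_CONSENSUS_PATTERN = ProteinPattern.from_string("EAR-consensus", "[LF]DLN[LF]xP")

BUILTIN_PATTERNS: dict[str, ProteinPattern] = {
    "IGT": igt_pattern(),
    "WxxTD": WXXTD_PATTERN,
    "EAR-LxLxL": ear_lxlxl_pattern(),
    "EAR-consensus": EAR_CONSENSUS_PATTERN,
}

#: Named EAR-like C-terminal motifs and their classes.  KLHTLIPNK does not
#: satisfy the strict LxLxL test; it is recognized by name because the family
#: literature explicitly calls it EAR-like.
DEFAULT_EAR_REGISTRY: dict[str, str] = {
    "IVLEM": CANONICAL,
    "IVLEI": CANONICAL,
    "KLHTLIPNK": EXTENDED,
}


def load_ear_registry(path: str | Path) -> dict[str, str]:
    """User-extensible registry TSV with columns ``motif`` and ``class``."""
    registry: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"motif", "class"}.issubset(reader.fieldnames):
            raise ValueError(f"EAR registry {path} must have columns motif, class")
        for row in reader:
            registry[row["motif"].upper()] = row["class"]
    return registry


@dataclass(frozen=True)
class ProteinMotifCall:
    """One protein motif match with C-terminal EAR classification."""

    protein_id: str
    motif_name: str
    start: int  # 1-based residue position; 0 when nothing matched
    matched: str
    cterm_class: str = NONE


def _matches_at(sequence: str, i: int, pattern: ProteinPattern) -> bool:
    # X in the sequence matches nothing
    for el, ch in zip(pattern.elements, sequence[i : i + len(pattern)]):
        if ch == "X":
            return False
        if el is not None and ch not in el:
            return False
    return True


def scan_protein(
    sequence: str, pattern: ProteinPattern, protein_id: str = ""
) -> list[ProteinMotifCall]:
    """All (overlapping) matches of ``pattern``, sorted by 1-based start."""
    sequence = sequence.upper()
    bad = set(sequence) - STANDARD_AA - {"X"}
    if bad:
        raise ValueError(f"invalid residues in sequence: {sorted(bad)}")
    calls = []
    for i in range(len(sequence) - len(pattern) + 1):
        if _matches_at(sequence, i, pattern):
            calls.append(
                ProteinMotifCall(
                    protein_id=protein_id,
                    motif_name=pattern.name,
                    start=i + 1,
                    matched=sequence[i : i + len(pattern)],
                )
            )
    return calls


def classify_cterm_ear(
    sequence: str,
    tail_length: int = 15,
    registry: Mapping[str, str] | None = None,
    hydrophobic: frozenset[str] = EAR_HYDROPHOBIC,
    protein_id: str = "",
) -> ProteinMotifCall:
    """Classify the extreme C-terminus as extended / canonical / divergent / none.

    Only the last ``tail_length`` residues are inspected.  Precedence:
    a registry motif carrying the IPNK suffix wins (extended), then an
    LxLxL-type Phi-x-Phi-x-Phi match (canonical), then any other registry
    motif (divergent); otherwise none.
    """
    if len(sequence) < 5:
        raise ValueError("sequence shorter than 5 residues")
    if registry is None:
        registry = DEFAULT_EAR_REGISTRY
    sequence = sequence.upper()
    offset = max(0, len(sequence) - tail_length)
    tail = sequence[offset:]

    def _call(motif_name: str, tail_idx: int, matched: str, klass: str) -> ProteinMotifCall:
        return ProteinMotifCall(
            protein_id=protein_id,
            motif_name=motif_name,
            start=offset + tail_idx + 1,
            matched=matched,
            cterm_class=klass,
        )

    # extended: registry entries with the IPNK suffix (rightmost occurrence)
    for motif in sorted(registry, key=len, reverse=True):
        if motif.endswith("IPNK"):
            idx = tail.rfind(motif)
            if idx != -1:
                return _call(motif, idx, motif, EXTENDED)
    # canonical: LxLxL-type match closest to the C-terminus
    lxlxl = ear_lxlxl_pattern(hydrophobic)
    match_starts = [
        i for i in range(len(tail) - len(lxlxl) + 1) if _matches_at(tail, i, lxlxl)
    ]
    if match_starts:
        i = match_starts[-1]
        return _call("EAR-LxLxL", i, tail[i : i + len(lxlxl)], CANONICAL)
    # divergent: any other registry motif present in the tail
    for motif in sorted(registry, key=len, reverse=True):
        idx = tail.rfind(motif)
        if idx != -1:
            return _call(motif, idx, motif, DIVERGENT)
    return ProteinMotifCall(protein_id=protein_id, motif_name="", start=0, matched="")


def truncate_cterm(
    sequence: str, motif_call: ProteinMotifCall, tail_length: int = 15
) -> str:
    """Remove the EAR-like motif and everything C-terminal of it.

    Mirrors the truncated constructs used to abolish TOPLESS interaction
    (e.g. a 251-aa protein ending IVLEM yields a 246-aa product).
    """
    if motif_call.cterm_class == NONE or motif_call.start == 0:
        raise ValueError("no C-terminal motif to remove")
    start0 = motif_call.start - 1
    if sequence.upper()[start0 : start0 + len(motif_call.matched)] != motif_call.matched:
        raise ValueError(
            f"motif {motif_call.matched} not found at position {motif_call.start}"
        )
    if start0 + len(motif_call.matched) < len(sequence) - tail_length:
        raise ValueError("motif not terminal")
    return sequence[:start0]


@dataclass(frozen=True)
class ConservedBlock:
    """A maximal run of well-conserved alignment columns (candidate domain)."""

    msa_column_span: tuple[int, int]  # 1-based inclusive
    mean_conservation: float
    domain_index: str  # "I".."V" or "unassigned"


_ROMAN = ["I", "II", "III", "IV", "V"]


def conserved_blocks(
    msa: Sequence[tuple[str, str]] | Sequence[str],
    threshold: float = 0.7,
    min_block_length: int = 5,
) -> list[ConservedBlock]:
    """Find maximal runs of conserved columns in a protein MSA.

    Per-column conservation is the frequency of the modal non-gap residue
    among non-gap rows; columns with more than 50% gaps score 0.  Runs of at
    least ``min_block_length`` columns at or above ``threshold`` are returned
    N- to C-terminal; the first five are labelled I-V.
    """
    rows = [r[1] if isinstance(r, tuple) else r for r in msa]
    if len(rows) < 2:
        raise ValueError("need at least 2 aligned sequences")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("ragged alignment")
    rows = [r.upper() for r in rows]

    scores = []
    for col in range(length):
        column = [r[col] for r in rows]
        non_gap = [c for c in column if c != GAP]
        if len(non_gap) * 2 < len(column):  # > 50% gaps
            scores.append(0.0)
            continue
        counts: dict[str, int] = {}
        for c in non_gap:
            counts[c] = counts.get(c, 0) + 1
        scores.append(max(counts.values()) / len(non_gap))

    blocks: list[ConservedBlock] = []
    run_start = None
    for col in range(length + 1):
        good = col < length and scores[col] >= threshold
        if good and run_start is None:
            run_start = col
        elif not good and run_start is not None:
            if col - run_start >= min_block_length:
                mean = sum(scores[run_start:col]) / (col - run_start)
                blocks.append(ConservedBlock((run_start + 1, col), mean, "unassigned"))
            run_start = None
    return [
        ConservedBlock(b.msa_column_span, b.mean_conservation,
                       _ROMAN[i] if i < 5 else "unassigned")
        for i, b in enumerate(blocks)
    ]
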