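"""Sequence I/O and the ATG-anchored coordinate model.

All positions reported to users follow the signed convention used throughout
the study of *DRO1-like* regulatory regions: the base immediately 5' of the
start codon is -1, and the A of ATG is +1 (there is no position 0).  Promoters
are the (up to) 2 kb of sequence immediately upstream of ATG on the coding
strand.  Internally everything is 0-based half-open on the locus sequence;
signed coordinates appear only at I/O boundaries.

A :class:`LocusRecord` holds a coding-strand genomic sequence together with
its ATG anchor and exon structure (exon 1 starts at the ATG), which is enough
to classify any sub-span as promoter, exon, intron, or spanning.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROMOTER = "promoter"
EXON = "exon"
INTRON = "intron"
SPANNING = "spanning"
REGION_LABELS = (PROMOTER, EXON, INTRON, SPANNING)

DNA_IUPAC = frozenset("ACGTRYSWKMBDHVN")
DNA_STRICT = frozenset("ACGTN")
PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"

_ALPHABETS = {
    "dna": DNA_IUPAC,
    "dna-strict": DNA_STRICT,
    "dna-aligned": DNA_IUPAC | {GAP},
    "protein": PROTEIN_LETTERS,
    "protein-aligned": PROTEIN_LETTERS | {GAP},
    None: None,
}


def read_fasta(path: str | Path, alphabet: str | None = "dna") -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into ``[(id, sequence), ...]`` in file order.

    Ids are the full header lines minus the leading ``>``; sequences are
    uppercased.  ``alphabet`` selects the validation set ("dna", "dna-strict",
    "dna-aligned", "protein", "protein-aligned", or None to skip validation).

    Raises
    ------
    ValueError
        If the file contains no records, or a sequence contains a character
        outside the chosen alphabet (the error names the record and position).
    """
    allowed = _ALPHABETS[alphabet]
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        header = rec.description
        if allowed is not None:
            for pos, ch in enumerate(seq):
                if ch not in allowed:
                    raise ValueError(
                        f"record {header!r}: invalid character {ch!r} at position {pos + 1}"
                    )
        records.append((header, seq))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, wrapping at ``width`` columns."""
    seqrecords = [SeqRecord(Seq(s), id="", description=str(i)) for i, s in records]
    with open(path, "w") as fh:
        for rec in seqrecords:
            fh.write(f">{rec.description}\n")
            seq = str(rec.seq)
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


# --- signed ATG-anchored coordinates ------------------------------------------------------

def to_signed_position(index: int, atg_index: int) -> int:
    """Map a 0-based sequence index to the signed ATG-anchored coordinate.

    The base just upstream of ATG is -1; the A of ATG is +1.  Never returns 0.
    """
    if index < 0:
        raise ValueError("index must be >= 0")
    if index < atg_index:
        return index - atg_index
    return index - atg_index + 1


def signed_to_index(value: int, atg_index: int) -> int:
    """Inverse of :func:`to_signed_position`."""
    if value == 0:
        raise ValueError("signed positions are never 0")
    if value < 0:
        return atg_index + value
    return atg_index + value - 1


@dataclass(frozen=True)
class PromoterSequence:
    """Promoter region immediately 5' of ATG, with its signed span."""

    gene_id: str
    sequence: str
    span: tuple[int, int]  # (most_negative, -1) signed coordinates
    truncated: bool

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass
class LocusRecord:
    """Coding-strand genomic locus with an ATG anchor and exon structure.

    ``exons`` are 0-based half-open intervals on ``sequence``; exon 1 starts at
    ``atg_index`` (the locus model runs from ATG to the stop codon, introns
    included, with promoter sequence upstream).
    """

    id: str
    sequence: str
    atg_index: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - DNA_STRICT
        if bad:
            raise ValueError(f"locus {self.id}: non-ACGTN characters {sorted(bad)}")
        if self.atg_index < 0:
            raise ValueError(f"locus {self.id}: atg_index must be >= 0")
        if self.atg_index + 3 <= len(self.sequence):
            codon = self.sequence[self.atg_index : self.atg_index + 3]
            if codon != "ATG":
                raise ValueError(f"locus {self.id}: expected ATG at atg_index, found {codon}")
        self.exons = [(int(a), int(b)) for a, b in self.exons]
        prev_end = None
        for a, b in self.exons:
            if not (0 <= a < b <= len(self.sequence)):
                raise ValueError(f"locus {self.id}: exon ({a},{b}) out of bounds")
            if a < self.atg_index:
                raise ValueError(f"locus {self.id}: exon ({a},{b}) starts upstream of ATG")
            if prev_end is not None and a < prev_end:
                raise ValueError(f"locus {self.id}: exons overlap or are unsorted")
            prev_end = b
        if self.exons and self.exons[0][0] != self.atg_index:
            raise ValueError(f"locus {self.id}: exon 1 must start at the ATG")

    def __len__(self) -> int:
        return len(self.sequence)


def extract_promoter(locus: LocusRecord, length: int = 2000) -> PromoterSequence:
    """Return the ``min(length, atg_index)`` bases immediately 5' of ATG.

    ``truncated`` is True when the locus holds fewer than ``length`` upstream
    bases.  Raises ValueError when there is no upstream sequence at all.
    """
    if length <= 0:
        raise ValueError("promoter length must be positive")
    if locus.atg_index == 0:
        raise ValueError(f"locus {locus.id}: no upstream sequence")
    take = min(length, locus.atg_index)
    seq = locus.sequence[locus.atg_index - take : locus.atg_index]
    return PromoterSequence(
        gene_id=locus.id,
        sequence=seq,
        span=(-take, -1),
        truncated=take < length,
    )


def classify_region(span: tuple[int, int], locus: LocusRecord) -> str:
    """Label a 0-based half-open span as promoter/exon/intron/spanning.

    A span is a promoter hit only if it lies entirely upstream of the ATG, an
    exon hit only if it sits inside a single exon, and an intron hit only if it
    sits inside a single inter-exon gap; everything else (junction-crossing
    spans, spans downstream of the last exon) is "spanning".
    """
    start, end = span
    if not (0 <= start < end <= len(locus.sequence)):
        raise ValueError(f"span {span} out of bounds for locus {locus.id}")
    if end <= locus.atg_index:
        return PROMOTER
    for a, b in locus.exons:
        if start >= a and end <= b:
            return EXON
    for (a1, b1), (a2, b2) in zip(locus.exons, locus.exons[1:]):
        if start >= b1 and end <= a2:
            return INTRON
    return SPANNING


# --- exon tables --------------------------------------------------------------------------

def read_exon_table(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a TSV with columns gene_id, exon_start, exon_end (1-based inclusive).

    Returns 0-based half-open intervals per gene, sorted by start.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "exon_start", "exon_end"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"exon table {path} must have columns {sorted(required)}")
        for row in reader:
            start1 = int(row["exon_start"])
            end1 = int(row["exon_end"])
            if start1 < 1 or end1 < start1:
                raise ValueError(f"bad exon interval ({start1},{end1}) for {row['gene_id']}")
            exons.setdefault(row["gene_id"], []).append((start1 - 1, end1))
    for gene in exons:
        exons[gene].sort()
    return exons


def write_exon_table(exons: dict[str, Sequence[tuple[int, int]]], path: str | Path) -> None:
    """Write the exon-table TSV (converting back to 1-based inclusive)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "exon_start", "exon_end"])
        for gene, ivals in exons.items():
            for a, b in ivals:
                writer.writerow([gene, a + 1, b])


def read_gff3_exons(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Convenience GFF3 importer: exon features grouped by seqid.

    Normalizes into the same 0-based half-open model as :func:`read_exon_table`;
    coordinates must be on the locus sequence itself (seqid == gene id).
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    exons: dict[str, list[tuple[int, int]]] = {}
    for feat in db.features_of_type("exon"):
        exons.setdefault(feat.seqid, []).append((feat.start - 1, feat.end))
    for gene in exons:
        exons[gene].sort()
    return exons


def load_loci(
    fasta_path: str | Path,
    exon_table_path: str | Path,
) -> dict[str, LocusRecord]:
    """Assemble :class:`LocusRecord` objects from a FASTA + exon table pair.

    The ATG anchor is the start of exon 1 (the locus model's invariant), so the
    exon table fully determines the coordinate frame.
    """
    exons = read_exon_table(exon_table_path)
    loci: dict[str, LocusRecord] = {}
    for header, seq in read_fasta(fasta_path, alphabet="dna-strict"):
        gene_id = header.split()[0].split("|")[0]
        if gene_id not in exons:
            raise ValueError(f"no exon rows for locus {gene_id}")
        gene_exons = exons[gene_id]
        loci[gene_id] = LocusRecord(
            id=gene_id,
            sequence=seq,
            atg_index=gene_exons[0][0],
            exons=gene_exons,
        )
    return loci


def promoter_fasta_header(promoter: PromoterSequence) -> str:
    """Header convention for promoter FASTA output: ``<gene>|promoter|<-L>..-1``."""
    return f"{promoter.gene_id}|promoter|{promoter.span[0]}..{promoter.span[1]}"
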