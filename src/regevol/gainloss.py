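"""Progenitor-to-descendant gain/loss ledger for cis-regulatory motifs.

Hexaploid wheat carries three homoeologous copies of each gene, contributed
by the A, B and D subgenome donors (T. urartu, Ae. speltoides-like, and
Ae. tauschii).  Comparing motif tallies between each diploid progenitor gene
and its wheat homoeolog gives a count-based ledger of cis-element gains and
losses — e.g. promoter TGTC deltas of +1, +1 and -1 along the A, B and D
lineages.  The ledger is purely count-based: it does not attempt positional
orthology of individual motif instances.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .motifscan import MotifTally


@dataclass(frozen=True)
class LineageEdge:
    parent: str
    child: str
    label: str = ""


@dataclass
class LineageMap:
    """Ordered progenitor->descendant edges; a child appears at most once."""

    edges: list[LineageEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edges = [
            e if isinstance(e, LineageEdge) else LineageEdge(*e) for e in self.edges
        ]
        children = [e.child for e in self.edges]
        if len(children) != len(set(children)):
            raise ValueError("a child gene appears on more than one edge")
        for e in self.edges:
            if e.parent == e.child:
                raise ValueError(f"self-edge {e.parent!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LineageMap":
        edges = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or not {"parent", "child"}.issubset(reader.fieldnames):
                raise ValueError(f"lineage map {path} must have columns parent, child[, label]")
            for row in reader:
                edges.append(LineageEdge(row["parent"], row["child"], row.get("label", "") or ""))
        return cls(edges)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["parent", "child", "label"])
            for e in self.edges:
                writer.writerow([e.parent, e.child, e.label])


@dataclass(frozen=True)
class LedgerEntry:
    parent: str
    child: str
    label: str
    motif: str
    region: str
    parent_count: int
    child_count: int

    @property
    def delta(self) -> int:
        return self.child_count - self.parent_count


@dataclass
class GainLossLedger:
    """Per-edge, per-(motif, region) count deltas."""

    entries: list[LedgerEntry] = field(default_factory=list)

    _COLUMNS = ["parent", "child", "label", "motif", "region",
                "parent_count", "child_count", "delta"]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(self._COLUMNS)
            for e in self.entries:
                writer.writerow([e.parent, e.child, e.label, e.motif, e.region,
                                 e.parent_count, e.child_count, e.delta])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GainLossLedger":
        entries = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                entry = LedgerEntry(
                    parent=row["parent"], child=row["child"], label=row["label"],
                    motif=row["motif"], region=row["region"],
                    parent_count=int(row["parent_count"]),
                    child_count=int(row["child_count"]),
                )
                if entry.delta != int(row["delta"]):
                    raise ValueError(f"inconsistent delta in row {row}")
                entries.append(entry)
        return cls(entries)


def delta_counts(parent: MotifTally, child: MotifTally, motif: str, region: str) -> int:
    """Child count minus parent count for one (motif, region); missing keys are 0."""
    return child.count(motif, region) - parent.count(motif, region)


def build_ledger(
    lineages: LineageMap, tallies: Mapping[str, MotifTally]
) -> GainLossLedger:
    """One ledger entry per (edge, motif, region) present in either tally.

    Entries are ordered by edge order, then motif name, then region name.
    """
    entries: list[LedgerEntry] = []
    for edge in lineages.edges:
        for gene in (edge.parent, edge.child):
            if gene not in tallies:
                raise ValueError(f"no tally for gene {gene!r}")
        parent_t, child_t = tallies[edge.parent], tallies[edge.child]
        keys = sorted(set(parent_t.counts) | set(child_t.counts))
        for motif, region in keys:
            entries.append(
                LedgerEntry(
                    parent=edge.parent, child=edge.child, label=edge.label,
                    motif=motif, region=region,
                    parent_count=parent_t.count(motif, region),
                    child_count=child_t.count(motif, region),
                )
            )
    return GainLossLedger(entries)


def annotate_expression_rank(
    ledger: GainLossLedger, ranks: Mapping[str, str]
) -> list[dict[str, object]]:
    """Join qualitative expression labels (+, ++, +++) onto ledger rows.

    The label belongs to the child (descendant) gene; missing genes get "NA".
    No computation is performed on the ranks.
    """
    rows = []
    for e in ledger.entries:
        rows.append(
            {
                "parent": e.parent, "child": e.child, "label": e.label,
                "motif": e.motif, "region": e.region,
                "parent_count": e.parent_count, "child_count": e.child_count,
                "delta": e.delta,
                "expression_rank": ranks.get(e.child, "NA"),
            }
        )
    return rows
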