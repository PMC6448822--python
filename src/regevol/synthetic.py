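"""Synthetic data with exact ground truth for every pipeline stage.

Each generator emits a :class:`TruthTable` alongside its data, so scanner
recall, ledger reconstruction, domain detection, tree inference and fold
recovery can all be checked against programmed truth without any downloads.

Design choices that keep truth tables exact: motif gains are realized by
overwriting (not inserting) so coordinates stay comparable across a family;
point substitutions are masked inside planted motifs (a ``mask_substitutions=
False`` mode exists for robustness testing); and backgrounds are scrubbed of
accidental pattern matches, so recall on truth instances is exactly 100% with
zero false positives.  Generators never emit IUPAC-ambiguous bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import csv

import numpy as np
import pandas as pd

from . import seqio
from .gainloss import LedgerEntry, LineageEdge, LineageMap
from .motifscan import BUILTIN_MOTIFS, IUPAC_SETS, MotifPattern
from .seqio import LocusRecord, signed_to_index, to_signed_position

BASES = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedInstance:
    """One motif occurrence the generator guarantees to be present."""

    gene_id: str
    motif_name: str
    position: int  # signed ATG-anchored coordinate
    region: str


@dataclass
class TruthTable:
    """Programmed ground truth emitted next to each synthetic dataset."""

    instances: list[PlantedInstance] = field(default_factory=list)
    ledger: list[LedgerEntry] = field(default_factory=list)
    tree: str | None = None
    folds: dict[str, float] | None = None
    ear_classes: dict[str, str] | None = None
    domain_spans: dict[str, tuple[int, int]] | None = None

    def instances_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["gene_id", "motif_name", "position", "region"])
            for inst in self.instances:
                writer.writerow([inst.gene_id, inst.motif_name, inst.position, inst.region])


# --- helpers ------------------------------------------------------------------------------

def _realize(pattern: MotifPattern, rng: np.random.Generator) -> str:
    """A concrete A/C/G/T instance of an IUPAC pattern."""
    out = []
    for code in pattern.pattern:
        choices = sorted(IUPAC_SETS[code] - {"N"}) or sorted(IUPAC_SETS[code])
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def _naive_matches(seq: str, pattern: MotifPattern) -> list[int]:
    """Generator-internal position-by-position matcher (independent of the
    production scanner); sequence N matches nothing."""
    hits = []
    plen = len(pattern)
    for i in range(len(seq) - plen + 1):
        ok = True
        for off, code in enumerate(pattern.pattern):
            base = seq[i + off]
            if base == "N" or base not in IUPAC_SETS[code]:
                ok = False
                break
        if ok:
            hits.append(i)
    return hits


def _covered(i: int, spans: Sequence[tuple[int, int]]) -> bool:
    return any(a <= i < b for a, b in spans)


def _scrub(
    seq: list[str],
    protected: Sequence[tuple[int, int]],
    patterns: Sequence[MotifPattern],
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> None:
    """Mutate accidental pattern matches (any base outside protected spans)
    until none remain.  Protected bases are never touched, so matches fully
    inside planted motifs survive as derived truth."""
    for _ in range(max_rounds):
        dirty = False
        text = "".join(seq)
        for pat in patterns:
            for start in _naive_matches(text, pat):
                span_idx = [start + k for k in range(len(pat))]
                outside = [k for k in span_idx if not _covered(k, protected)]
                if not outside:
                    continue  # derived truth inside a planted motif
                k = outside[int(rng.integers(len(outside)))]
                old = seq[k]
                seq[k] = BASES[int(rng.integers(4))]
                while seq[k] == old:
                    seq[k] = BASES[int(rng.integers(4))]
                dirty = True
        if not dirty:
            return
        # re-scan: scrub mutations may have created new matches
    raise RuntimeError("background scrub did not converge")


def _disrupt(
    seq: list[str], span: tuple[int, int], pattern: MotifPattern, rng: np.random.Generator
) -> None:
    """Single-base disruption of a planted motif so it no longer matches."""
    start, _ = span
    # prefer a constrained pattern position, where one substitution is decisive
    offsets = sorted(
        range(len(pattern)),
        key=lambda off: len(IUPAC_SETS[pattern.pattern[off]]),
    )
    off = offsets[0]
    allowed = IUPAC_SETS[pattern.pattern[off]]
    forbidden = sorted(set(BASES) - allowed)
    if not forbidden:  # fully degenerate position: any base matches; pick another offset
        raise ValueError(f"cannot disrupt fully degenerate pattern {pattern.name}")
    seq[start + off] = forbidden[int(rng.integers(len(forbidden)))]


# --- regulatory family --------------------------------------------------------------------

@dataclass
class RegulatoryFamily:
    """A simulated progenitor/descendant gene family with exact motif truth."""

    loci: dict[str, LocusRecord]
    exons: dict[str, list[tuple[int, int]]]
    lineages: LineageMap
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seqio.write_fasta(
            [(gene, locus.sequence) for gene, locus in self.loci.items()],
            outdir / "loci.fasta",
        )
        seqio.write_exon_table(self.exons, outdir / "exons.tsv")
        self.lineages.to_tsv(outdir / "lineages.tsv")
        self.truth.instances_tsv(outdir / "truth_instances.tsv")


def simulate_regulatory_family(
    progenitor_id: str = "progenitor",
    promoter_length: int = 2000,
    exon_lengths: Sequence[int] = (300, 200, 150, 100, 250),
    intron_lengths: Sequence[int] = (500, 400, 300, 200),
    plant_spec: Iterable[tuple[str, int]] = (),
    lineage_spec: Iterable[tuple[str, str, str, Sequence[tuple[str, int]], Sequence[tuple[str, int]]]] = (),
    sub_rate: float = 0.01,
    seed: int = 0,
    motifs: Mapping[str, MotifPattern] | None = None,
    mask_substitutions: bool = True,
) -> RegulatoryFamily:
    """Simulate a gene family with planted motifs and programmed gains/losses.

    The progenitor locus is a uniform-composition promoter (``promoter_length``
    bp) followed by alternating exons and introns (exon 1 starts at the ATG,
    which mirrors the five-exon/four-intron structure typical of these loci).
    ``plant_spec`` lists (motif_name, signed_position) plants for the
    progenitor; each ``lineage_spec`` entry is (parent, child, label, gains,
    losses) applied in order, where gains overwrite fresh motif instances and
    losses disrupt a planted instance with a single substitution.  Descendants
    additionally accumulate point substitutions at ``sub_rate`` per base
    outside planted motifs (inside them too with ``mask_substitutions=False``).
    Deterministic for a fixed seed.
    """
    if len(intron_lengths) != len(exon_lengths) - 1:
        raise ValueError("need exactly one fewer intron than exons")
    if motifs is None:
        motifs = BUILTIN_MOTIFS
    patterns = list(motifs.values())
    rng = np.random.default_rng(seed)

    # locus geometry, shared by the whole family
    atg = promoter_length
    exons: list[tuple[int, int]] = []
    pos = atg
    for k, elen in enumerate(exon_lengths):
        exons.append((pos, pos + elen))
        pos += elen
        if k < len(intron_lengths):
            pos += intron_lengths[k]
    total = pos

    def make_locus(gene: str, seq: str) -> LocusRecord:
        return LocusRecord(id=gene, sequence=seq, atg_index=atg, exons=list(exons))

    probe = make_locus("_probe", "A" * atg + "ATG" + "A" * (total - atg - 3))

    def plant(seq: list[str], gene: str, spans: dict[tuple[str, int], tuple[int, int]],
              motif_name: str, signed_pos: int) -> None:
        pat = motifs[motif_name]
        start = signed_to_index(signed_pos, atg)
        span = (start, start + len(pat))
        if span[0] < 0 or span[1] > total:
            raise ValueError(f"{gene}: plant {motif_name}@{signed_pos} out of bounds")
        region = seqio.classify_region(span, probe)
        if region == seqio.SPANNING:
            raise ValueError(f"{gene}: plant {motif_name}@{signed_pos} spans a boundary")
        for other in list(spans.values()) + [(atg, atg + 3)]:
            if span[0] < other[1] and other[0] < span[1]:
                raise ValueError(
                    f"{gene}: plant {motif_name}@{signed_pos} overlaps another planted span"
                )
        seq[span[0] : span[1]] = list(_realize(pat, rng))
        spans[(motif_name, signed_pos)] = span

    genomes: dict[str, list[str]] = {}
    planted: dict[str, dict[tuple[str, int], tuple[int, int]]] = {}

    # progenitor
    base = [BASES[int(b)] for b in rng.integers(0, 4, size=total)]
    base[atg : atg + 3] = list("ATG")
    spans: dict[tuple[str, int], tuple[int, int]] = {}
    for motif_name, signed_pos in plant_spec:
        plant(base, progenitor_id, spans, motif_name, signed_pos)
    protected = list(spans.values()) + [(atg, atg + 3)]
    _scrub(base, protected, patterns, rng)
    genomes[progenitor_id] = base
    planted[progenitor_id] = spans

    edges: list[LineageEdge] = []
    for parent, child, label, gains, losses in lineage_spec:
        if parent not in genomes:
            raise ValueError(f"edge {parent}->{child}: unknown parent {parent!r}")
        seq = list(genomes[parent])
        spans = dict(planted[parent])
        for motif_name, signed_pos in losses:
            key = (motif_name, signed_pos)
            if key not in spans:
                raise ValueError(f"{child}: loss of unplanted {motif_name}@{signed_pos}")
            _disrupt(seq, spans.pop(key), motifs[motif_name], rng)
        for motif_name, signed_pos in gains:
            plant(seq, child, spans, motif_name, signed_pos)
        protected = list(spans.values()) + [(atg, atg + 3)]
        if sub_rate > 0:
            mask = np.zeros(total, dtype=bool)
            if mask_substitutions:
                for a, b in protected:
                    mask[a:b] = True
            else:
                mask[atg : atg + 3] = True
            hit = rng.random(total) < sub_rate
            for k in np.flatnonzero(hit & ~mask):
                old = seq[k]
                new = BASES[int(rng.integers(4))]
                while new == old:
                    new = BASES[int(rng.integers(4))]
                seq[k] = new
        _scrub(seq, protected, patterns, rng)
        genomes[child] = seq
        planted[child] = spans
        edges.append(LineageEdge(parent, child, label))

    # truth instances: every pattern match that lies fully inside a planted span
    loci = {gene: make_locus(gene, "".join(seq)) for gene, seq in genomes.items()}
    instances: list[PlantedInstance] = []
    truth_counts: dict[str, dict[tuple[str, str], int]] = {}
    for gene, locus in loci.items():
        counts: dict[tuple[str, str], int] = {}
        prot = list(planted[gene].values())
        for pat in patterns:
            for start in _naive_matches(locus.sequence, pat):
                span = (start, start + len(pat))
                if not all(_covered(k, prot) for k in range(span[0], span[1])):
                    continue
                region = seqio.classify_region(span, locus)
                instances.append(
                    PlantedInstance(gene, pat.name, to_signed_position(start, atg), region)
                )
                counts[(pat.name, region)] = counts.get((pat.name, region), 0) + 1
        truth_counts[gene] = counts

    ledger_entries: list[LedgerEntry] = []
    for edge in edges:
        keys = sorted(set(truth_counts[edge.parent]) | set(truth_counts[edge.child]))
        for motif_name, region in keys:
            ledger_entries.append(
                LedgerEntry(
                    parent=edge.parent, child=edge.child, label=edge.label,
                    motif=motif_name, region=region,
                    parent_count=truth_counts[edge.parent].get((motif_name, region), 0),
                    child_count=truth_counts[edge.child].get((motif_name, region), 0),
                )
            )

    return RegulatoryFamily(
        loci=loci,
        exons={gene: list(exons) for gene in loci},
        lineages=LineageMap(edges),
        truth=TruthTable(instances=instances, ledger=ledger_entries),
    )


#: Lineage scenario mirroring the tritici story: three diploid donors derived
#: from a hypothetical progenitor, then the three wheat homoeologs with
#: promoter-TGTC deltas +1 (A), +1 (B) and -1 (D).
TRITICI_LINEAGE_SPEC: tuple = (
    ("BdDRO1", "TuDRO1", "A-origin", (), ()),
    ("BdDRO1", "AsDRO1", "B-origin",
     (("TGTCTC", -1802), ("TGTC", -367), ("TGTC", -938), ("AuxRE-like", -1100)), ()),
    ("BdDRO1", "AtaDRO1", "D-origin", (("TGTC", -372), ("TGTC", -1708)), ()),
    ("TuDRO1", "TaADRO1", "A", (("TGTC", -853),), ()),
    ("AsDRO1", "TaBDRO1", "B", (("TGTC", -926),), ()),
    ("AtaDRO1", "TaDDRO1", "D", (), (("TGTC", -372),)),
)


def tritici_family(seed: int = 0, sub_rate: float = 0.01) -> RegulatoryFamily:
    """Preset family emulating the wheat homoeolog scenario with known truth."""
    return simulate_regulatory_family(
        progenitor_id="BdDRO1",
        plant_spec=(("TGTC", -772), ("TGTC", 452), ("TGTC", 510)),
        lineage_spec=TRITICI_LINEAGE_SPEC,
        sub_rate=sub_rate,
        seed=seed,
    )


# --- protein family -----------------------------------------------------------------------

DEFAULT_DOMAIN_TEMPLATE: dict[str, str] = {
    "I": "MKIFDWVRSE",
    "II": "SGILAGTPRE",   # contains the IGT motif GILAGT
    "III": "DQHENLSARW",
    "IV": "TPGNWESQRK",
    "V": "LEWAATDKRQ",    # contains the WxxTD instance WAATD
}

DEFAULT_EAR_ASSIGNMENT = ("IVLEM", "KLHTLIPNK", "IVLEM", "KLHTLIPNK", "IVLEI", "none")

_EAR_TRUTH_CLASS = {"IVLEM": "canonical", "IVLEI": "canonical",
                    "KLHTLIPNK": "extended", "none": "none"}


@dataclass
class ProteinFamily:
    """A simulated protein family with planted domains and EAR C-termini."""

    records: list[tuple[str, str]]
    alignment: list[tuple[str, str]]
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seqio.write_fasta(self.records, outdir / "proteins.fasta")
        seqio.write_fasta(self.alignment, outdir / "proteins_aln.fasta")


def simulate_protein_family(
    n: int = 6,
    domain_template: Mapping[str, str] | None = None,
    ear_assignment: Sequence[str] | None = None,
    seed: int = 0,
    linker_length: int = 8,
    tail_length: int = 12,
) -> ProteinFamily:
    """Simulate proteins sharing five conserved domains and assigned C-termini.

    Members share the domain blocks verbatim, separated by per-member random
    linkers, and end in the assigned EAR-like motif (IVLEM, IVLEI, KLHTLIPNK,
    or "none").  All members have equal length, so the emitted alignment is
    gap-free by construction.  Members assigned "none" draw their tail from
    non-hydrophobic residues so no spurious LxLxL-type match can arise.
    """
    if domain_template is None:
        domain_template = DEFAULT_DOMAIN_TEMPLATE
    if ear_assignment is None:
        ear_assignment = tuple(DEFAULT_EAR_ASSIGNMENT[k % len(DEFAULT_EAR_ASSIGNMENT)]
                               for k in range(n))
    if len(ear_assignment) != n:
        raise ValueError("ear_assignment must have one entry per member")
    for motif in ear_assignment:
        if motif not in _EAR_TRUTH_CLASS:
            raise ValueError(f"unknown EAR assignment {motif!r}")
    if tail_length < max(len(m) for m in _EAR_TRUTH_CLASS if m != "none"):
        raise ValueError("tail_length too short for the longest EAR motif")

    rng = np.random.default_rng(seed)
    blocks = [domain_template[k] for k in ("I", "II", "III", "IV", "V")]
    no_phi = "".join(sorted(set(AA20) - set("LIVM")))

    records: list[tuple[str, str]] = []
    ear_classes: dict[str, str] = {}
    for k in range(n):
        member = f"p{k + 1}"
        motif = ear_assignment[k]
        parts = []
        for bi, block in enumerate(blocks):
            parts.append(block)
            if bi < len(blocks) - 1:
                parts.append("".join(AA20[int(i)] for i in rng.integers(0, 20, linker_length)))
        if motif == "none":
            tail = "".join(no_phi[int(i)] for i in rng.integers(0, len(no_phi), tail_length))
        else:
            pad = tail_length - len(motif)
            tail = "".join(AA20[int(i)] for i in rng.integers(0, 20, pad)) + motif
        records.append((member, "".join(parts) + tail))
        ear_classes[member] = _EAR_TRUTH_CLASS[motif]

    # planted domain column spans (1-based inclusive) — identical across members
    spans: dict[str, tuple[int, int]] = {}
    col = 1
    for name, block in zip(("I", "II", "III", "IV", "V"), blocks):
        spans[name] = (col, col + len(block) - 1)
        col += len(block) + (linker_length if name != "V" else 0)

    truth = TruthTable(ear_classes=ear_classes, domain_spans=spans)
    return ProteinFamily(records=records, alignment=list(records), truth=truth)


# --- alignment down a tree ----------------------------------------------------------------

def simulate_alignment(
    tree: str,
    seq_length: int,
    seed: int = 0,
    model: str = "jc",
) -> list[tuple[str, str]]:
    """Evolve an alignment down a newick tree under Jukes-Cantor.

    The root sequence is uniform over A/C/G/T; along a branch of length t
    (substitutions/site) each site changes with probability
    (3/4)(1 - exp(-4t/3)), to one of the three other bases uniformly.  Leaves
    are emitted in tree (preorder) order.  Deterministic for a fixed seed.
    """
    import dendropy

    if model != "jc":
        raise ValueError(f"unknown model {model!r}")
    try:
        t = dendropy.Tree.get(data=tree, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc

    rng = np.random.default_rng(seed)
    base_idx = {node: None for node in t.preorder_node_iter()}
    root_seq = rng.integers(0, 4, size=seq_length)
    out: list[tuple[str, str]] = []
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            base_idx[node] = root_seq
        else:
            parent_seq = base_idx[node.parent_node]
            blen = node.edge.length or 0.0
            p_change = 0.75 * (1.0 - np.exp(-4.0 * blen / 3.0))
            seq = parent_seq.copy()
            hit = np.flatnonzero(rng.random(seq_length) < p_change)
            if hit.size:
                # jump to one of the three other bases uniformly
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=hit.size)) % 4
            base_idx[node] = seq
        if node.is_leaf():
            label = node.taxon.label if node.taxon else "?"
            out.append((label, "".join(BASES[i] for i in base_idx[node])))
    return out


# --- qPCR Ct tables -----------------------------------------------------------------------

def simulate_ct_table(
    true_folds: Mapping[str, float],
    target: str = "TaBDRO1-like",
    references: Sequence[str] = ("elf", "tubulin"),
    replicates: int = 3,
    ref_baselines: Sequence[float] = (19.0, 21.0),
    target_offset: float = 5.0,
    ref_stability_sd: float = 0.0,
    tech_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format Ct table with programmed fold changes.

    ``true_folds`` maps sample_id to its fold relative to the calibrator (the
    calibrator entry is 1.0).  Reference Cts are drawn around fixed baselines
    with an optional per-sample stability shift; the target Ct is offset by
    -log2(fold); technical noise is Gaussian with sd ``tech_sd`` cycles.
    With both sd values at 0 the folds are recovered exactly.
    """
    if len(references) != len(ref_baselines):
        raise ValueError("need one baseline per reference gene")
    for sample, fold in true_folds.items():
        if fold <= 0:
            raise ValueError(f"fold for {sample!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    ref_mean_baseline = float(np.mean(ref_baselines))
    for sample, fold in true_folds.items():
        shift = rng.normal(0.0, ref_stability_sd) if ref_stability_sd > 0 else 0.0
        for rep in range(1, replicates + 1):
            for ref, baseline in zip(references, ref_baselines):
                noise = rng.normal(0.0, tech_sd) if tech_sd > 0 else 0.0
                rows.append((sample, sample, "synthetic", ref, rep,
                             baseline + shift + noise))
            noise = rng.normal(0.0, tech_sd) if tech_sd > 0 else 0.0
            ct_target = ref_mean_baseline + target_offset - np.log2(fold) + noise
            rows.append((sample, sample, "synthetic", target, rep, ct_target))
    return pd.DataFrame(
        rows, columns=["sample_id", "tissue", "genotype", "gene", "replicate", "ct"]
    )
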