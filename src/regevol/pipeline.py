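"""End-to-end orchestration of the two report artifacts.

``run_table1`` turns loci + exon structure into the per-gene AuxRE position
report (Table-1 layout) plus a composite-element table; ``run_fig6`` turns
that report plus a lineage map into the gain/loss ledger and a one-line-per-
edge summary.  Runs are deterministic and every run writes a provenance block
(config hash, seed, package version) sufficient to reproduce the outputs
byte-for-byte.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__, motifscan, seqio
from .gainloss import GainLossLedger, LineageMap, annotate_expression_rank, build_ledger
from .motifscan import BUILTIN_MOTIFS, read_motif_tsv, read_table1_report
from .seqio import INTRON, PROMOTER

log = logging.getLogger("regevol")


@dataclass
class RunConfig:
    """Paths and parameters for a pipeline run."""

    loci: str | None = None
    exons: str | None = None
    lineages: str | None = None
    expression_ranks: str | None = None
    motifs: str = "builtin"
    promoter_length: int = 2000
    composite_window: int = 250
    seed: int = 0
    outdir: str = "regevol_out"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        extra = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        return cls(**known, extra=extra) if "extra" not in known else cls(**known)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_provenance(config: RunConfig, outdir: Path, artifact: str) -> None:
    prov = {
        "artifact": artifact,
        "config_hash": config.digest(),
        "config": asdict(config),
        "seed": config.seed,
        "version": __version__,
    }
    with open(outdir / f"{artifact}.provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)


def _load_patterns(config: RunConfig):
    if config.motifs == "builtin":
        return dict(BUILTIN_MOTIFS)
    if config.motifs in ("none", ""):
        return {}
    return read_motif_tsv(config.motifs)


def run_table1(config: RunConfig) -> tuple[Path, Path]:
    """Scan every locus and write table1.tsv + composites.tsv under outdir."""
    if not config.loci or not config.exons:
        raise ValueError("run_table1 needs loci and exons paths")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patterns = _load_patterns(config)
    loci = seqio.load_loci(config.loci, config.exons)
    log.info("scanning %d loci: motifs=%s promoter_length=%d window=%d",
             len(loci), sorted(patterns), config.promoter_length, config.composite_window)

    tallies = []
    composite_rows = []
    for gene, locus in loci.items():
        try:
            hits = motifscan.scan_gene(locus, patterns.values(), config.promoter_length)
        except Exception as exc:
            raise RuntimeError(f"gene {gene}: {exc}") from exc
        tallies.append(motifscan.tally(hits, gene_id=gene))
        for comp in motifscan.detect_composite(hits, window=config.composite_window):
            composite_rows.append([
                gene, comp.coupling_hit.motif_name, comp.coupling_hit.position,
                comp.auxre_hit.motif_name, comp.auxre_hit.position, comp.gap,
            ])

    table1_path = outdir / "table1.tsv"
    motifscan.write_table1_report(tallies, table1_path)
    composites_path = outdir / "composites.tsv"
    with open(composites_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene", "coupling_motif", "coupling_position",
                         "auxre_motif", "auxre_position", "gap_bp"])
        writer.writerows(composite_rows)
    _write_provenance(config, outdir, "table1")
    return table1_path, composites_path


def run_fig6(config: RunConfig, table1_path: str | Path | None = None) -> tuple[Path, Path]:
    """Build the gain/loss ledger + summary from a Table-1 report and lineage map."""
    if not config.lineages:
        raise ValueError("run_fig6 needs a lineages path")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table1_path is None:
        table1_path = outdir / "table1.tsv"
    tallies = {t.gene_id: t for t in read_table1_report(table1_path)}
    lineages = LineageMap.from_tsv(config.lineages)
    ledger = build_ledger(lineages, tallies)

    ranks = {}
    if config.expression_ranks:
        with open(config.expression_ranks, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                ranks[row["gene_id"]] = row["rank"]
    rows = annotate_expression_rank(ledger, ranks)

    ledger_path = outdir / "ledger.tsv"
    with open(ledger_path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, delimiter="\t",
            fieldnames=["parent", "child", "label", "motif", "region",
                        "parent_count", "child_count", "delta", "expression_rank"],
        )
        writer.writeheader()
        writer.writerows(rows)

    summary_path = outdir / "summary.txt"
    with open(summary_path, "w") as fh:
        for e in ledger.entries:
            if e.region in (PROMOTER, INTRON):
                fh.write(
                    f"{e.parent}->{e.child}: {e.region} {e.motif} {e.delta:+d}\n"
                )
    _write_provenance(config, outdir, "fig6")
    return ledger_path, summary_path
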