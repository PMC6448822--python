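"""Quantitative assay computations: qPCR fold expression, Miller units, stats.

Relative expression uses the 2^-ddCt method with one or more reference genes
(here typically *elf* and *tubulin*): per replicate, dCt is the target Ct
minus the arithmetic mean of the reference Cts (equivalent to the geometric
mean of reference quantities); ddCt subtracts the calibrator sample's mean
dCt; the reported fold is 2^(-mean ddCt), so the calibrator's fold is exactly
1 by construction, with the sd taken across per-replicate folds.
Amplification efficiency is fixed at 2.

Beta-galactosidase activity uses the Miller-unit formula
U = 1000 * OD420 / (t[min] * V[ml] * OD600).

Group comparisons use the Welch unequal-variance t statistic with
Welch-Satterthwaite degrees of freedom (a pooled-variance Student option is
available by flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = {"sample_id", "gene", "replicate", "ct"}


def _validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    missing = CT_COLUMNS - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if ct.duplicated(subset=["sample_id", "gene", "replicate"]).any():
        raise ValueError("duplicate (sample, gene, replicate) rows")
    return ct


@dataclass(frozen=True)
class FoldExpression:
    """Per-sample normalized fold expression (2^-ddCt) with replicate sd."""

    sample_id: str
    gene: str
    fold: float
    sd: float


def fold_expression(
    ct: pd.DataFrame,
    target: str,
    references: Sequence[str],
    calibrator: str,
) -> list[FoldExpression]:
    """Normalized fold expression of ``target`` against one or more references.

    ``ct`` is a long-format table with columns sample_id, gene, replicate, ct
    (extra columns such as tissue/genotype are carried along untouched).
    The calibrator sample's fold is exactly 1.
    """
    ct = _validate_ct_table(ct)
    samples = list(dict.fromkeys(ct["sample_id"]))
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    genes_needed = [target, *references]
    per_sample_genes = ct.groupby("sample_id")["gene"].agg(set)
    for sample in samples:
        for gene in genes_needed:
            if gene not in per_sample_genes[sample]:
                raise ValueError(f"gene {gene!r} missing for sample {sample!r}")

    wide = ct.pivot_table(index=["sample_id", "replicate"], columns="gene",
                          values="ct", aggfunc="first")
    ref_mean = wide[list(references)].mean(axis=1)
    dct = wide[target] - ref_mean
    calib_dct = float(dct.xs(calibrator, level="sample_id").mean())

    results = []
    for sample in samples:
        ddct = dct.xs(sample, level="sample_id").dropna() - calib_dct
        rep_folds = np.power(2.0, -ddct.to_numpy())
        fold = float(2.0 ** (-ddct.mean()))
        sd = float(np.std(rep_folds, ddof=1)) if len(rep_folds) > 1 else 0.0
        results.append(FoldExpression(sample_id=sample, gene=target, fold=fold, sd=sd))
    return results


@dataclass(frozen=True)
class AssayReading:
    """One beta-galactosidase assay reading."""

    od420: float
    od600: float
    time_min: float
    volume_ml: float

    def __post_init__(self) -> None:
        if self.od600 <= 0:
            raise ValueError("od600 must be positive")
        if self.time_min <= 0:
            raise ValueError("time must be positive")
        if self.volume_ml <= 0:
            raise ValueError("volume must be positive")


def miller_units(r: AssayReading) -> float:
    """U = 1000 * OD420 / (t[min] * V[ml] * OD600)."""
    return 1000.0 * r.od420 / (r.time_min * r.volume_ml * r.od600)


def welch_t(
    a: Sequence[float], b: Sequence[float], pooled: bool = False
) -> tuple[float, float, float]:
    """Two-sided t test: Welch by default, pooled Student with ``pooled=True``.

    Returns (t, df, p).  Each group needs n >= 2 and nonzero variance.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 measurements")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise ValueError("degenerate group with zero variance")
    nx, ny = len(x), len(y)
    if pooled:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = math.sqrt(sp2 * (1 / nx + 1 / ny))
        df = float(nx + ny - 2)
    else:
        se = math.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    t = (x.mean() - y.mean()) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def summarize_morphometrics(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(genotype, trait) mean, sample sd and n for measurement tables.

    ``table`` has columns genotype, trait, value.  A group with a single value
    reports sd 0 and n 1.  Non-numeric values raise an error naming the row.
    """
    required = {"genotype", "trait", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"morphometrics table missing columns {sorted(missing)}")
    values = pd.to_numeric(table["value"], errors="coerce")
    bad = values.isna() & table["value"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-numeric value in row {row + 1}")
    work = table.assign(value=values)
    out = (
        work.groupby(["genotype", "trait"], sort=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out
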