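"""Population-level statistics for single-cell growth-rate distributions.

Heterogeneity measures (coefficient of variation, top/bottom quintile
contrasts), correlation wrappers, and two-sample distribution tests, plus
the tabular population summary used by the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "quintile_factor",
    "speedup_factor",
    "cv",
    "cv_summary",
    "correlate",
    "CorrelationResult",
    "compare_distributions",
    "summarize_population",
]

logger = logging.getLogger(__name__)


def _quantile_group_sizes(n: int, q: float) -> int:
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    return math.ceil(q * n)


def quintile_factor(rates, q: float = 0.2, stat: str = "mean") -> float:
    """Fold difference between the most and least active cells.

    Mean (or median, ``stat="median"``) of the top ``ceil(q*n)`` values
    divided by that of the bottom ``ceil(q*n)`` values after a stable
    descending sort.  NaN (with a warning) if the bottom-group mean is not
    positive.
    """
    v = np.asarray(rates, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 values")
    k = _quantile_group_sizes(v.size, q)
    order = np.argsort(-v, kind="stable")
    agg = np.mean if stat == "mean" else np.median
    top = agg(v[order[:k]])
    bottom = agg(v[order[-k:]])
    if bottom <= 0:
        logger.warning("bottom-quantile %s is not positive; factor undefined", stat)
        return float("nan")
    return float(top / bottom)


def speedup_factor(rates, q: float = 0.2, stat: str = "mean") -> float:
    """Fold increase if every cell were as active as the top ``q`` fraction.

    Mean (or median) of the top ``ceil(q*n)`` values divided by the
    population mean (or median).
    """
    v = np.asarray(rates, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 values")
    k = _quantile_group_sizes(v.size, q)
    order = np.argsort(-v, kind="stable")
    agg = np.mean if stat == "mean" else np.median
    whole = agg(v)
    if whole <= 0:
        raise ValueError("population mean must be positive")
    return float(agg(v[order[:k]]) / whole)


def cv(values) -> float:
    """Coefficient of variation: sample standard deviation (n-1) over mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / m)


def cv_summary(per_replicate_cvs) -> tuple[float, float]:
    """Mean CV across replicates and its standard error ``sd/sqrt(k)``."""
    c = np.asarray(per_replicate_cvs, dtype=float)
    if c.size == 0:
        raise ValueError("no replicate CVs supplied")
    sem = float(c.std(ddof=1) / math.sqrt(c.size)) if c.size > 1 else float("nan")
    return float(c.mean()), sem


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    method: str


def correlate(x, y, method: str = "spearman") -> CorrelationResult:
    """Spearman (average ranks for ties) or Pearson correlation, two-sided p.

    Pairs containing non-finite values are dropped.  Zero variance in either
    vector yields a NaN coefficient with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance in one vector; correlation undefined")
        return CorrelationResult(float("nan"), float("nan"), n, method)
    if method == "spearman":
        r = sps.spearmanr(x, y)
    elif method == "pearson":
        r = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(r.statistic), float(r.pvalue), n, method)


def compare_distributions(a, b) -> dict[str, float]:
    """Two-sided Kolmogorov-Smirnov and Mann-Whitney U tests between samples.

    Returns a dict with ``ks_statistic``, ``ks_p``, ``mwu_statistic`` (U of
    the first sample), ``mwu_p``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    ks = sps.ks_2samp(a, b)
    mwu = sps.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "mwu_statistic": float(mwu.statistic),
        "mwu_p": float(mwu.pvalue),
    }


def _summary_row(group: pd.DataFrame, label: str) -> dict:
    row: dict = {"replicate": label, "n_cells": len(group)}
    for name in ("mu_total", "mu_glc", "mu_ara"):
        v = group[name].to_numpy(dtype=float)
        row[f"mean_{name}"] = float(v.mean())
        row[f"cv_{name}"] = cv(v) if v.size >= 2 and v.mean() > 0 else float("nan")
    s = group["s"].to_numpy(dtype=float)
    s = s[np.isfinite(s)]
    row["fraction_s_negative"] = float(np.mean(s < 0)) if s.size else float("nan")
    mu = group["mu_total"].to_numpy(dtype=float)
    row["quintile_factor"] = quintile_factor(mu) if mu.size >= 5 else float("nan")
    row["speedup_factor"] = speedup_factor(mu) if mu.size >= 5 else float("nan")
    return row


def summarize_population(estimates: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate and pooled summary of a cell-estimate table.

    One row per replicate (if a ``replicate_id`` column is present) plus a
    ``pooled`` row; columns give cell counts, mean and CV of each growth
    rate, the arabinose-preferring fraction (``s < 0``), and the quintile
    heterogeneity factors.  The pooled row also carries the across-replicate
    mean CV of ``mu_total`` and its SEM.
    """
    rows = []
    per_rep_cvs = []
    if "replicate_id" in estimates.columns and estimates["replicate_id"].nunique() > 1:
        for rep, grp in estimates.groupby("replicate_id", sort=True):
            row = _summary_row(grp, str(rep))
            rows.append(row)
            if np.isfinite(row["cv_mu_total"]):
                per_rep_cvs.append(row["cv_mu_total"])
    pooled = _summary_row(estimates, "pooled")
    if per_rep_cvs:
        mean_cv, sem_cv = cv_summary(per_rep_cvs)
        pooled["replicate_mean_cv_mu_total"] = mean_cv
        pooled["replicate_sem_cv_mu_total"] = sem_cv
    rows.append(pooled)
    return pd.DataFrame(rows)
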