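"""Per-cell excess atom fractions from NanoSIMS region-of-interest ion counts.

Input is the tabular export of upstream image processing: accumulated ion
counts (1H, 2H, 12C, 13C) per cell ROI, plus per-field outside-ROI atom
fractions of the analyzed filter and of an unlabeled reference filter.
This module computes raw atom fractions, corrects per image for instrument
drift against the reference filter, subtracts natural abundance to obtain
excess atom fractions, and applies Poisson counting-error quality control.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .experiment import NaturalAbundance

__all__ = [
    "atom_fraction",
    "poisson_ratio_error_pct",
    "drift_correct",
    "excess_fraction",
    "process_counts",
    "qc_filter",
    "COUNT_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Required ion-count columns of the per-ROI counts table.
COUNT_COLUMNS = ("c1H", "c2H", "c12C", "c13C")

#: QC thresholds: Poisson percentage error of the 2H/1H count ratio must be
#: below 10% and that of the 13C/12C ratio below 1%.
MAX_ERR_PCT_HH = 10.0
MAX_ERR_PCT_CH = 1.0


def atom_fraction(heavy, light):
    """Atom fraction ``heavy / (heavy + light)`` from accumulated ion counts.

    Works element-wise on arrays.  Raises on a zero denominator for scalar
    input; array input yields NaN for empty ROIs (callers must drop them).
    """
    heavy = np.asarray(heavy, dtype=float)
    light = np.asarray(light, dtype=float)
    total = heavy + light
    if total.ndim == 0:
        if total == 0:
            raise ValueError("empty ROI: zero total ion counts for the element")
        return float(heavy / total)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, heavy / total, np.nan)


def poisson_ratio_error_pct(a, b):
    """Poisson percentage error of the count ratio ``a/b``.

    For independent Poisson counts the relative error of the ratio is
    ``sqrt(1/a + 1/b)``, reported in percent.  Zero counts give infinite
    error (the record then fails QC rather than crashing).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(divide="ignore"):
        err = 100.0 * np.sqrt(np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), np.inf)
                              + np.where(b > 0, 1.0 / np.where(b > 0, b, 1.0), np.inf))
    if err.ndim == 0:
        return float(err)
    return err


def drift_correct(x_uncorrected, x_filter_cells, x_filter_reference):
    """Correct an atom fraction for day-to-day instrument drift.

    Subtracts the difference between the outside-ROI atom fraction of the
    analyzed filter and that of the unlabeled reference filter::

        x_cell = x_uncorrected - (x_filter_cells - x_filter_reference)

    The correction is a per-image constant shift, so within-image ranking of
    cells is preserved.
    """
    return x_uncorrected - (np.asarray(x_filter_cells) - np.asarray(x_filter_reference))


def excess_fraction(x_corrected, x_natural):
    """Excess atom fraction: enrichment above unlabeled biomass.

    ``x_corrected - x_natural``; a cell of natural isotopic composition maps
    to zero.  Slightly negative values are legitimate measurement noise and
    are retained.
    """
    return np.asarray(x_corrected, dtype=float) - x_natural


def _filter_lookup(filters: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Split the filter table into per-field backgrounds and the reference.

    Expects columns ``field_id, x13C_filter, x2H_filter, is_reference``.
    Multiple rows per field (or reference) are averaged with a warning.
    """
    required = {"field_id", "x13C_filter", "x2H_filter", "is_reference"}
    missing = required - set(filters.columns)
    if missing:
        raise ValueError(f"filter table is missing columns: {sorted(missing)}")
    for col in ("x13C_filter", "x2H_filter"):
        vals = filters[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"filter table column {col} contains values outside [0, 1]")
    is_ref = filters["is_reference"].astype(int) == 1
    ref = filters.loc[is_ref]
    if ref.empty:
        raise ValueError("filter table contains no reference record (is_reference=1)")
    if len(ref) > 1:
        logger.warning("averaging %d reference-filter records", len(ref))
    x13C_ref = float(ref["x13C_filter"].mean())
    x2H_ref = float(ref["x2H_filter"].mean())

    per_field = filters.loc[~is_ref]
    dup = per_field["field_id"].duplicated()
    if dup.any():
        logger.warning(
            "multiple filter-background records for field(s) %s; using the mean",
            sorted(per_field.loc[dup, "field_id"].unique()),
        )
    bg = per_field.groupby("field_id", sort=False)[["x13C_filter", "x2H_filter"]].mean()
    return bg, x13C_ref, x2H_ref


def process_counts(
    counts: pd.DataFrame,
    filters: pd.DataFrame,
    natural: NaturalAbundance | None = None,
    max_err_HH: float = MAX_ERR_PCT_HH,
    max_err_CH: float = MAX_ERR_PCT_CH,
) -> pd.DataFrame:
    """Turn a per-ROI counts table into a per-cell isotope measurement table.

    Parameters
    ----------
    counts
        One row per ROI with columns ``replicate_id, field_id, roi_id,
        c1H, c2H, c12C, c13C`` (extra columns such as fluorescence are
        carried through).
    filters
        Outside-ROI atom fractions per field plus one reference record;
        see :func:`_filter_lookup`.
    natural
        Natural-abundance atom fractions to subtract.
    max_err_HH, max_err_CH
        QC bounds (percent, strict ``<``) on the Poisson error of the
        2H/1H and 13C/12C count ratios.

    Returns
    -------
    DataFrame with uncorrected/corrected/excess atom fractions, Poisson
    percentage errors, and a ``qc_pass`` flag, one row per valid ROI.
    Rows whose total carbon or hydrogen counts are zero are dropped with a
    warning (empty/invalid ROIs).
    """
    natural = natural or NaturalAbundance()
    for col in COUNT_COLUMNS:
        if col not in counts.columns:
            raise ValueError(f"counts table is missing column {col!r}")
        if (counts[col] < 0).any():
            raise ValueError(f"negative ion counts in column {col!r}")

    out = counts.copy()
    total_C = out["c12C"] + out["c13C"]
    total_H = out["c1H"] + out["c2H"]
    bad = (total_C == 0) | (total_H == 0)
    if bad.any():
        logger.warning("dropping %d ROI(s) with zero total counts", int(bad.sum()))
        out = out.loc[~bad].copy()

    bg, x13C_ref, x2H_ref = _filter_lookup(filters)
    missing_fields = sorted(set(out["field_id"]) - set(bg.index))
    if missing_fields:
        raise KeyError(
            f"no filter background for field_id(s): {missing_fields}"
        )
    field_bg = bg.loc[out["field_id"]]

    out["x13C_uncorrected"] = atom_fraction(out["c13C"], out["c12C"])
    out["x2H_uncorrected"] = atom_fraction(out["c2H"], out["c1H"])
    out["x13C_corrected"] = drift_correct(
        out["x13C_uncorrected"].to_numpy(),
        field_bg["x13C_filter"].to_numpy(),
        x13C_ref,
    )
    out["x2H_corrected"] = drift_correct(
        out["x2H_uncorrected"].to_numpy(),
        field_bg["x2H_filter"].to_numpy(),
        x2H_ref,
    )
    out["xE13C"] = excess_fraction(out["x13C_corrected"], natural.x13C)
    out["xE2H"] = excess_fraction(out["x2H_corrected"], natural.x2H)
    out["err_pct_CH"] = poisson_ratio_error_pct(out["c13C"], out["c12C"])
    out["err_pct_HH"] = poisson_ratio_error_pct(out["c2H"], out["c1H"])
    out["qc_pass"] = (out["err_pct_HH"] < max_err_HH) & (out["err_pct_CH"] < max_err_CH)
    return out


def qc_filter(
    measurements: pd.DataFrame,
    max_err_HH: float = MAX_ERR_PCT_HH,
    max_err_CH: float = MAX_ERR_PCT_CH,
) -> pd.DataFrame:
    """Keep only cells whose Poisson count-ratio errors are within bounds.

    Strict inequalities, so a record exactly at a threshold is removed.
    Idempotent: the output always satisfies its own filter.
    """
    keep = (measurements["err_pct_HH"] < max_err_HH) & (
        measurements["err_pct_CH"] < max_err_CH
    )
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "QC removed %d of %d cells (err_HH < %g%%, err_CH < %g%%)",
            n_removed, len(measurements), max_err_HH, max_err_CH,
        )
    return measurements.loc[keep].copy()
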