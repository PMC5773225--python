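"""Paired reporter-fluorescence / isotope-assimilation specialization analysis.

Cells carry two transcriptional reporters (an arabinose-uptake promoter
driving GFP and a glucose-PTS promoter driving mCherry) and are measured on
the same filter by fluorescence microscopy and NanoSIMS.  This module
corrects fluorescence for filter background and cell autofluorescence,
standardizes all four channels (mCherry, GFP, xE2H, xE13C) per field of
view, min-max normalizes the combined standardized values to [0, 1], and
contrasts each pair into a specialization index:

* transcriptional specialization = (mCherry' - GFP') / (mCherry' + GFP')
* sugar specialization = (xE2H' - xE13C') / (xE2H' + xE13C')

where primes denote the [0, 1]-normalized values.  Both indices point the
same way: +1 is pure glucose preference, -1 pure arabinose preference.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "correct_fluorescence",
    "standardize_per_field",
    "normalize_unit_range",
    "specialization_pair",
    "pair_cells",
    "CHANNELS",
]

logger = logging.getLogger(__name__)

#: The four per-cell channels entering the paired analysis.
CHANNELS = ("corrected_mcherry", "corrected_gfp", "xE2H", "xE13C")


def correct_fluorescence(
    cells: pd.DataFrame, backgrounds: pd.DataFrame
) -> pd.DataFrame:
    """Subtract filter background and cell autofluorescence per channel.

    ``corrected = raw - filter_background - autofluorescence``.  Negative
    corrected values are retained (flagged in ``negative_fluorescence``)
    since clipping would bias per-field means.

    Parameters
    ----------
    cells
        Per-cell table with ``field_id``, ``gfp``, ``mcherry`` columns.
    backgrounds
        Per-field table with ``field_id``, ``bg_gfp``, ``bg_mcherry``,
        ``auto_gfp``, ``auto_mcherry``.
    """
    required = {"field_id", "bg_gfp", "bg_mcherry", "auto_gfp", "auto_mcherry"}
    missing = required - set(backgrounds.columns)
    if missing:
        raise ValueError(f"background table is missing columns: {sorted(missing)}")
    bg = backgrounds.drop_duplicates("field_id").set_index("field_id")
    missing_fields = sorted(set(cells["field_id"]) - set(bg.index))
    if missing_fields:
        raise KeyError(f"no fluorescence background for field_id(s): {missing_fields}")
    out = cells.copy()
    b = bg.loc[out["field_id"]]
    out["corrected_gfp"] = (
        out["gfp"].to_numpy(dtype=float)
        - b["bg_gfp"].to_numpy()
        - b["auto_gfp"].to_numpy()
    )
    out["corrected_mcherry"] = (
        out["mcherry"].to_numpy(dtype=float)
        - b["bg_mcherry"].to_numpy()
        - b["auto_mcherry"].to_numpy()
    )
    out["negative_fluorescence"] = (out["corrected_gfp"] < 0) | (
        out["corrected_mcherry"] < 0
    )
    n_neg = int(out["negative_fluorescence"].sum())
    if n_neg:
        logger.info("%d cell(s) have negative corrected fluorescence (kept)", n_neg)
    return out


def standardize_per_field(
    cells: pd.DataFrame,
    channels=CHANNELS,
    field_col: str = "field_id",
) -> pd.DataFrame:
    """Z-score each channel within each field of view.

    Within every (field, channel) group: ``z = (v - mean) / sd`` using the
    sample (n-1) standard deviation, so each group has mean 0 and sd 1.
    Fields with fewer than 2 cells, or a constant channel, cannot be
    standardized and are dropped with a warning.

    Returns the table restricted to usable fields, with ``z_<channel>``
    columns appended.
    """
    out = cells.copy()
    drop_fields: set = set()
    for field, grp in out.groupby(field_col, sort=False):
        if len(grp) < 2:
            drop_fields.add(field)
            continue
        for ch in channels:
            if grp[ch].std(ddof=1) == 0:
                drop_fields.add(field)
                break
    if drop_fields:
        logger.warning(
            "excluding field(s) %s: singleton or constant channel",
            sorted(map(str, drop_fields)),
        )
        out = out.loc[~out[field_col].isin(drop_fields)].copy()
    if out.empty:
        raise ValueError("no field has >= 2 cells with non-constant channels")
    for ch in channels:
        g = out.groupby(field_col, sort=False)[ch]
        out[f"z_{ch}"] = (out[ch] - g.transform("mean")) / g.transform("std")
    return out


def normalize_unit_range(values: np.ndarray) -> np.ndarray:
    """Min-max normalize a combined value set to [0, 1].

    ``v' = (v - min) / (max - min)``; the extreme inputs map exactly to 0
    and 1.  The set must contain at least two distinct values.
    """
    v = np.asarray(values, dtype=float)
    vmin, vmax = np.nanmin(v), np.nanmax(v)
    if vmax == vmin:
        raise ValueError("cannot normalize a constant value set")
    return (v - vmin) / (vmax - vmin)


def specialization_pair(mcherry_norm, gfp_norm, xE2H_norm, xE13C_norm):
    """Contrast two normalized channel pairs into specialization indices.

    Returns ``(transcriptional, sugar)`` arrays, each
    ``(first - second) / (first + second)`` on [-1, 1]; NaN where the
    denominator is not positive (such cells are excluded from correlations).
    """
    def _contrast(p, q):
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        denom = p + q
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (p - q) / np.where(denom > 0, denom, 1.0), np.nan)

    return _contrast(mcherry_norm, gfp_norm), _contrast(xE2H_norm, xE13C_norm)


def pair_cells(
    measurements: pd.DataFrame,
    backgrounds: pd.DataFrame,
    channels=CHANNELS,
) -> pd.DataFrame:
    """Full paired analysis: correct, standardize, normalize, contrast.

    ``measurements`` must hold raw ``gfp`` / ``mcherry`` intensities and the
    excess atom fractions ``xE2H`` / ``xE13C`` per cell, with ``field_id``.
    Cells missing any of the four channels are dropped (only cells with
    complete overlap between the fluorescence and NanoSIMS images enter the
    analysis).

    Returns the per-cell table with standardized (``z_``), [0,1]-normalized
    (``norm_``) channels and both specialization indices.
    """
    cells = correct_fluorescence(measurements, backgrounds)
    complete = cells.dropna(subset=list(channels))
    n_dropped = len(cells) - len(complete)
    if n_dropped:
        logger.info("dropped %d cell(s) lacking one of the four channels", n_dropped)
    z = standardize_per_field(complete, channels=channels)

    zcols = [f"z_{ch}" for ch in channels]
    combined = z[zcols].to_numpy(dtype=float)
    normed = normalize_unit_range(combined.ravel()).reshape(combined.shape)
    for j, ch in enumerate(channels):
        z[f"norm_{ch}"] = normed[:, j]

    transcriptional, sugar = specialization_pair(
        z["norm_corrected_mcherry"],
        z["norm_corrected_gfp"],
        z["norm_xE2H"],
        z["norm_xE13C"],
    )
    z["transcriptional_specialization"] = transcriptional
    z["sugar_specialization"] = sugar
    return z
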