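"""Mass-balance model linking per-cell isotope enrichment to growth rates.

Forward model
-------------
A cell grows exponentially during the labeling period ``T`` at total rate
``mu_total = mu_glc + mu_ara + mu_AOC``, so the fraction of its biomass that
is newly made is ``f_new = 1 - exp(-mu_total * T)``.  New biomass draws its
carbon from the sugar pathways and from assimilable organic carbon (AOC) in
proportion to the corresponding growth rates.  Carbon assimilated through
the arabinose pathway carries the washout-averaged heavy-carbon purity of
the medium arabinose, attenuated by the transfer coefficient ``kappa_C``
(the remainder of new carbon comes from unlabeled AOC); hydrogen from the
glucose pathway carries the averaged deuterium purity attenuated by
``eta_H`` (the remainder diluted by AOC hydrogen and exchange with water).
The measurable excess atom fractions are therefore

.. math::

    X^E(^{13}C) = \\frac{\\mu_{ara}}{\\mu_{tot}} f_{new}\\,
        \\kappa_C (\\bar p_{ara} - x^{nat}_{13C}),
    \\qquad
    X^E(^{2}H) = \\frac{\\mu_{glc}}{\\mu_{tot}} f_{new}\\,
        \\eta_H (\\bar p_{glc} - x^{nat}_{2H}),

with :math:`\\bar p` the washout-averaged label purity of each sugar.

Inversion
---------
Normalizing each excess fraction by its channel gain gives
``A = (mu_ara/mu_total) f_new`` and ``G = (mu_glc/mu_total) f_new``, so

.. math:: A + G = (1 - \\mu_{AOC}/\\mu_{tot})\\,(1 - e^{-\\mu_{tot} T}),

which is strictly increasing in ``mu_total`` on ``(mu_AOC, inf)`` and is
solved by bracketed root finding; the sugar rates then follow in closed
form.  The specialization index contrasts availability-normalized glucose
and arabinose assimilation on ``[-1, 1]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .experiment import LabelCalibration, LabelingExperiment, NaturalAbundance, calibrate

__all__ = [
    "channel_gains",
    "forward_model",
    "invert_cell",
    "invert_table",
    "specialization_index",
    "CellEstimate",
    "SingleCellLabelingModel",
    "LabelingResults",
]

logger = logging.getLogger(__name__)

#: Absolute tolerance (1/h) of the mu_total root finder.
ROOT_XTOL = 1e-10
#: The search interval for mu_total is (mu_AOC, CAP_FACTOR * mu_max].
CAP_FACTOR = 5.0


def channel_gains(
    exp: LabelingExperiment,
    cal: LabelCalibration,
    natural: NaturalAbundance | None = None,
) -> tuple[float, float]:
    """Per-channel enrichment gains ``kappa_C*(p_ara_bar - x13C_nat)`` and
    ``eta_H*(p_glc_bar - x2H_nat)``.

    These convert the dimensionless assimilation terms ``(mu/mu_total)*f_new``
    into excess atom fractions.
    """
    natural = natural or NaturalAbundance()
    if not cal.is_calibrated:
        raise ValueError("calibration has no transfer coefficients; run calibrate()")
    p_ara_bar = exp.mean_purity(exp.p_ara, natural.x13C)
    p_glc_bar = exp.mean_purity(exp.p_glc, natural.x2H)
    gain_C = cal.kappa_C * (p_ara_bar - natural.x13C)
    gain_H = cal.eta_H * (p_glc_bar - natural.x2H)
    return gain_C, gain_H


def forward_model(
    mu_glc,
    mu_ara,
    exp: LabelingExperiment,
    cal: LabelCalibration,
    natural: NaturalAbundance | None = None,
):
    """Predict per-cell excess atom fractions ``(xE13C, xE2H)``.

    Vectorized over ``mu_glc`` / ``mu_ara`` (broadcast together).  Both
    outputs are strictly increasing in their own sugar rate and decreasing
    in the other (dilution through ``mu_total``).
    """
    mu_glc = np.asarray(mu_glc, dtype=float)
    mu_ara = np.asarray(mu_ara, dtype=float)
    if np.any(mu_glc < 0) or np.any(mu_ara < 0):
        raise ValueError("growth rates must be non-negative")
    gain_C, gain_H = channel_gains(exp, cal, natural)
    mu_total = mu_glc + mu_ara + exp.mu_AOC
    if np.any(mu_total <= 0):
        raise ValueError("mu_total must be positive")
    f_new = -np.expm1(-mu_total * exp.T_label)
    xE13C = (mu_ara / mu_total) * f_new * gain_C
    xE2H = (mu_glc / mu_total) * f_new * gain_H
    if xE13C.ndim == 0:
        return float(xE13C), float(xE2H)
    return xE13C, xE2H


def _assimilation_capacity(mu_total: float, mu_AOC: float, T: float) -> float:
    """``(1 - mu_AOC/mu_total) * (1 - exp(-mu_total*T))``, the sugar-derived
    new-biomass fraction; strictly increasing in ``mu_total`` above ``mu_AOC``."""
    return (1.0 - mu_AOC / mu_total) * (-np.expm1(-mu_total * T))


@dataclass(frozen=True)
class CellEstimate:
    """Inverted growth rates for one cell (all in 1/h)."""

    mu_glc: float
    mu_ara: float
    mu_AOC: float
    mu_total: float
    s: float
    converged: bool


def invert_cell(
    xE13C: float,
    xE2H: float,
    exp: LabelingExperiment,
    cal: LabelCalibration,
    natural: NaturalAbundance | None = None,
) -> CellEstimate:
    """Invert measured excess atom fractions into per-cell growth rates.

    Negative excess fractions (noise around zero) are clipped to zero before
    inversion.  ``converged=False`` with rates at the search cap flags cells
    whose combined enrichment exceeds what any growth rate up to
    ``CAP_FACTOR * mu_max`` could produce.
    """
    if not (np.isfinite(xE13C) and np.isfinite(xE2H)):
        raise ValueError("excess atom fractions must be finite")
    gain_C, gain_H = channel_gains(exp, cal, natural)
    A = max(float(xE13C), 0.0) / gain_C
    G = max(float(xE2H), 0.0) / gain_H
    T = exp.T_label
    mu_AOC = exp.mu_AOC

    if A + G == 0.0:
        return CellEstimate(0.0, 0.0, mu_AOC, mu_AOC, float("nan"), True)

    mu_cap = CAP_FACTOR * exp.mu_max
    lo = mu_AOC + 1e-12
    if A + G >= _assimilation_capacity(mu_cap, mu_AOC, T):
        # enrichment beyond the attainable maximum: pin the rates at the cap,
        # preserving the measured channel ratio
        mu_glc = (mu_cap - mu_AOC) * G / (A + G)
        mu_ara = (mu_cap - mu_AOC) * A / (A + G)
        s = specialization_index(mu_glc, mu_ara, exp.supply_glc, exp.supply_ara)
        return CellEstimate(mu_glc, mu_ara, mu_AOC, mu_cap, s, False)
    if A + G <= _assimilation_capacity(lo, mu_AOC, T):
        # enrichment below the bracket floor: mu_total is mu_AOC to within
        # the root tolerance and the sugar rates follow from A and G directly
        mu_total = lo
    else:
        mu_total = brentq(
            lambda mu: _assimilation_capacity(mu, mu_AOC, T) - (A + G),
            lo,
            mu_cap,
            xtol=ROOT_XTOL,
        )
    f_new = -np.expm1(-mu_total * T)
    mu_ara = A * mu_total / f_new
    mu_glc = G * mu_total / f_new
    s = specialization_index(mu_glc, mu_ara, exp.supply_glc, exp.supply_ara)
    return CellEstimate(mu_glc, mu_ara, mu_AOC, mu_glc + mu_ara + mu_AOC, s, True)


def specialization_index(mu_glc, mu_ara, supply_glc: float = 10.0, supply_ara: float = 10.0):
    """Degree of specialization ``s`` on ``[-1, 1]``.

    With availability-normalized rates ``g = mu_glc/supply_glc`` and
    ``a = mu_ara/supply_ara``::

        s = (g - a) / (g + a)

    ``s = -1``: the cell assimilates only arabinose; ``s = +1``: only
    glucose; ``s = 0``: sugars are assimilated in proportion to their
    availability.  Undefined (NaN) when both sugar rates are zero.
    """
    if supply_glc <= 0 or supply_ara <= 0:
        raise ValueError("sugar supplies must be positive")
    g = np.asarray(mu_glc, dtype=float) / supply_glc
    a = np.asarray(mu_ara, dtype=float) / supply_ara
    denom = g + a
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (g - a) / np.where(denom > 0, denom, 1.0), np.nan)
    if s.ndim == 0:
        return float(s)
    return s


def invert_table(
    measurements: pd.DataFrame,
    exp: LabelingExperiment,
    cal: LabelCalibration,
    natural: NaturalAbundance | None = None,
) -> pd.DataFrame:
    """Apply :func:`invert_cell` to every row of a measurement table.

    Expects ``xE13C`` and ``xE2H`` columns; identifier columns
    (``replicate_id``, ``field_id``, ``roi_id``) and the raw excess
    fractions are carried through.
    """
    est = [
        invert_cell(r.xE13C, r.xE2H, exp, cal, natural)
        for r in measurements.itertuples()
    ]
    out = measurements[
        [c for c in ("replicate_id", "field_id", "roi_id", "xE13C", "xE2H")
         if c in measurements.columns]
    ].copy()
    out["mu_glc"] = [e.mu_glc for e in est]
    out["mu_ara"] = [e.mu_ara for e in est]
    out["mu_AOC"] = [e.mu_AOC for e in est]
    out["mu_total"] = [e.mu_total for e in est]
    out["s"] = [e.s for e in est]
    out["converged"] = [e.converged for e in est]
    n_unconverged = int((~out["converged"]).sum())
    if n_unconverged:
        logger.warning(
            "%d cell(s) exceeded the attainable enrichment; rates capped", n_unconverged
        )
    return out


class SingleCellLabelingModel:
    """Per-cell growth-rate model for a dual-isotope labeling experiment.

    Built from a table of QC-passing per-cell excess atom fractions
    (``xE13C``, ``xE2H``); :meth:`fit` inverts the mass-balance model cell
    by cell and returns a :class:`LabelingResults`.

    Parameters
    ----------
    measurements
        Per-cell measurement table, e.g. the output of
        :func:`isocell.nanosims.process_counts`.
    experiment
        Culture/labeling constants.
    calibration
        Transfer coefficients; if the supplied calibration lacks them it is
        completed from its asymptotic enrichment values via
        :func:`isocell.experiment.calibrate`.
    apply_qc
        If True (default) and the table has a ``qc_pass`` column, only
        QC-passing cells are fitted.
    """

    def __init__(
        self,
        measurements: pd.DataFrame,
        experiment: LabelingExperiment | None = None,
        calibration: LabelCalibration | None = None,
        natural: NaturalAbundance | None = None,
        apply_qc: bool = True,
    ) -> None:
        for col in ("xE13C", "xE2H"):
            if col not in measurements.columns:
                raise ValueError(f"measurement table lacks column {col!r}")
        self.experiment = experiment or LabelingExperiment()
        self.natural = natural or NaturalAbundance()
        cal = calibration or LabelCalibration()
        if not cal.is_calibrated:
            cal = calibrate(cal, self.experiment, self.natural)
        self.calibration = cal
        self.n_input = len(measurements)
        if apply_qc and "qc_pass" in measurements.columns:
            measurements = measurements.loc[measurements["qc_pass"].astype(bool)]
            logger.info(
                "fitting %d of %d cells passing QC", len(measurements), self.n_input
            )
        self.measurements = measurements.reset_index(drop=True)

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        filters: pd.DataFrame,
        experiment: LabelingExperiment | None = None,
        calibration: LabelCalibration | None = None,
        natural: NaturalAbundance | None = None,
        **kwargs,
    ) -> "SingleCellLabelingModel":
        """Build the model straight from per-ROI ion counts and filter tables."""
        from .nanosims import process_counts

        meas = process_counts(counts, filters, natural=natural)
        return cls(meas, experiment, calibration, natural, **kwargs)

    def predict(self, mu_glc, mu_ara):
        """Forward-model excess atom fractions for given rates."""
        return forward_model(mu_glc, mu_ara, self.experiment, self.calibration, self.natural)

    def fit(self) -> "LabelingResults":
        """Invert the model for every cell and package the estimates."""
        estimates = invert_table(
            self.measurements, self.experiment, self.calibration, self.natural
        )
        return LabelingResults(self, estimates)


class LabelingResults:
    """Per-cell growth-rate estimates and population summaries.

    Attributes
    ----------
    estimates
        DataFrame with one row per fitted cell: ``mu_glc``, ``mu_ara``,
        ``mu_AOC``, ``mu_total`` (1/h), specialization ``s``, and a
        ``converged`` flag, plus carried-through identifiers and raw excess
        fractions.
    """

    def __init__(self, model: SingleCellLabelingModel, estimates: pd.DataFrame) -> None:
        self.model = model
        self.estimates = estimates

    @property
    def n_cells(self) -> int:
        return len(self.estimates)

    def population_summary(self) -> pd.DataFrame:
        """Pooled and per-replicate population statistics.

        See :func:`isocell.stats.summarize_population`.
        """
        from .stats import summarize_population

        return summarize_population(self.estimates)

    def summary(self) -> str:
        """Plain-text summary in the style of regression-results tables."""
        from .stats import cv, quintile_factor, speedup_factor

        est = self.estimates
        mu = est["mu_total"].to_numpy()
        s = est["s"].to_numpy()
        s_def = s[np.isfinite(s)]
        exp = self.model.experiment
        cal = self.model.calibration
        lines = [
            "Single-cell dual-isotope labeling model",
            "=" * 55,
            f"mode: {exp.mode:<12} T_label: {exp.T_label} h    mu_AOC: {exp.mu_AOC} 1/h",
            f"kappa_C: {cal.kappa_C:.4f}    eta_H: {cal.eta_H:.4f}",
            f"cells fitted: {self.n_cells} (of {self.model.n_input} input)",
            "-" * 55,
            f"{'':<12}{'mean':>10}{'CV':>10}",
        ]
        for name in ("mu_total", "mu_glc", "mu_ara"):
            v = est[name].to_numpy()
            cv_str = f"{cv(v):>10.3f}" if v.size >= 2 and v.mean() > 0 else f"{'n/a':>10}"
            lines.append(f"{name:<12}{np.mean(v):>10.4f}{cv_str}")
        lines += [
            "-" * 55,
            f"fraction s < 0 (arabinose-preferring): {np.mean(s_def < 0):.3f}"
            f"  (n={s_def.size})",
        ]
        if mu.size >= 5:
            lines += [
                f"top-vs-bottom quintile factor: {quintile_factor(mu):.2f}",
                f"top-quintile vs population speedup: {speedup_factor(mu):.2f}",
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<LabelingResults: {self.n_cells} cells>"
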