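"""Synthetic NanoSIMS experiments from a known ground-truth population.

Generates every table the pipeline consumes — per-ROI ion counts, per-field
filter backgrounds, reporter fluorescence with backgrounds — from a
population with known per-cell growth rates and specialization, so each
analysis stage can be tested for parameter recovery without any raw data.

The population model: total growth rate ``mu_total`` is the shared AOC rate
plus a lognormally distributed sugar-derived rate, parameterized so that
``mu_total`` has a chosen mean and coefficient of variation (lognormal:
positive and right-skewed, as expected for a strongly heterogeneous
population).  The specialization index ``s`` is a Gaussian clipped to
(-1, 1) — continuous and unimodal — and splits the sugar rate between
glucose and arabinose by inverting the specialization contrast.
Measurement noise is one Poisson draw per ion channel; per-field filter
drift offsets shift the expected fractions and are exactly recoverable by
the reference-filter correction.  Reporter fluorescence combines a shared
lognormal "global expression" factor (making the two raw channels
positively correlated) with channel terms tied to the cell's true ``s``
by a tunable coupling strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiment import LabelCalibration, LabelingExperiment, NaturalAbundance, calibrate
from .model import forward_model

__all__ = [
    "PopulationSpec",
    "sample_population",
    "render_counts",
    "render_fluorescence",
    "simulate_experiment",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Ground-truth population and measurement-noise parameters.

    Parameters
    ----------
    n_cells
        Number of cells to simulate.
    mu_total_mean, mu_total_cv
        Mean (1/h) and coefficient of variation of the total single-cell
        growth rate (defaults: the carbon-limited chemostat population,
        mean 0.037 1/h, CV 0.724).
    s_mean, s_sd
        Location and scale of the clipped-Gaussian specialization
        distribution on (-1, 1).  Defaults put about 95% of cells at
        ``s < 0`` (arabinose-preferring).
    mu_AOC
        Shared AOC-derived growth rate (1/h); subtracted from ``mu_total``
        before splitting between the sugars.
    counts_C, counts_H
        Expected total carbon / hydrogen ion counts per cell ROI.  Defaults
        make the Poisson-error QC thresholds (1% carbon, 10% hydrogen)
        remove a small minority of poorly labeled cells.
    drift_13C, drift_2H
        Standard deviation of the per-field filter drift offsets (atom
        fraction units).
    coupling
        Strength in [0, 1] of the dependence of reporter expression on the
        cell's true specialization; 0 decouples transcription from
        assimilation.
    n_fields, n_replicates
        Cells are dealt round-robin onto fields, and fields round-robin
        onto replicates.
    """

    n_cells: int = 250
    mu_total_mean: float = 0.037
    mu_total_cv: float = 0.724
    s_mean: float = -0.30
    s_sd: float = 0.18
    mu_AOC: float = 0.010
    counts_C: float = 2e6
    counts_H: float = 3e5
    drift_13C: float = 5e-4
    drift_2H: float = 5e-5
    coupling: float = 0.7
    n_fields: int = 10
    n_replicates: int = 3
    global_expression_sd: float = 0.5
    channel_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if not self.mu_total_mean > self.mu_AOC >= 0:
            raise ValueError(
                "need mu_total_mean > mu_AOC >= 0: the mean sugar-derived rate "
                "would otherwise be non-positive"
            )
        if self.mu_total_cv <= 0:
            raise ValueError("mu_total_cv must be positive")
        if min(self.counts_C, self.counts_H) < 1e3:
            raise ValueError("expected ion counts must be >= 1000")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * sigma2, np.sqrt(sigma2)


def sample_population(
    spec: PopulationSpec, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Draw the ground-truth table of per-cell rates and specialization.

    ``mu_total = mu_AOC + X`` with ``X`` lognormal, scaled so that
    ``mu_total`` has mean ``mu_total_mean`` and CV ``mu_total_cv``; the AOC
    term is constant across cells so all variation sits in the sugar rates
    and every cell's sugar rate is strictly positive.  ``s`` is Gaussian
    clipped to (-0.999, 0.999); the sugar rate splits as
    ``mu_glc = X*(g)/(g+a)`` with availability-normalized shares recovered
    by inverting the specialization contrast (equal supplies give
    ``mu_glc = X*(1+s)/2``).
    """
    rng = np.random.default_rng(rng)
    exp = LabelingExperiment()  # supplies only; equal 10 uM defaults
    sugar_mean = spec.mu_total_mean - spec.mu_AOC
    sugar_sd = spec.mu_total_cv * spec.mu_total_mean
    mu_ln, sigma_ln = _lognormal_params(sugar_mean, sugar_sd)
    x_sugar = rng.lognormal(mu_ln, sigma_ln, size=spec.n_cells)

    s = rng.normal(spec.s_mean, spec.s_sd, size=spec.n_cells) if spec.s_sd > 0 \
        else np.full(spec.n_cells, spec.s_mean)
    s = np.clip(s, -0.999, 0.999)

    # invert s = (g - a)/(g + a) with g = mu_glc/supply_glc, a = mu_ara/supply_ara
    # under the constraint mu_glc + mu_ara = x_sugar
    g_share = (1.0 + s) / 2.0  # g / (g + a)
    w_glc = g_share * exp.supply_glc
    w_ara = (1.0 - g_share) * exp.supply_ara
    mu_glc = x_sugar * w_glc / (w_glc + w_ara)
    mu_ara = x_sugar * w_ara / (w_glc + w_ara)

    cell_idx = np.arange(spec.n_cells)
    field_idx = cell_idx % spec.n_fields
    rep_idx = field_idx % spec.n_replicates
    return pd.DataFrame(
        {
            "replicate_id": [f"R{i + 1}" for i in rep_idx],
            "field_id": [f"F{i + 1:02d}" for i in field_idx],
            "roi_id": [f"cell{i + 1:05d}" for i in cell_idx],
            "mu_glc": mu_glc,
            "mu_ara": mu_ara,
            "mu_AOC": spec.mu_AOC,
            "mu_total": mu_glc + mu_ara + spec.mu_AOC,
            "s": s,
        }
    )


def render_counts(
    truth: pd.DataFrame,
    spec: PopulationSpec,
    exp: LabelingExperiment | None = None,
    cal: LabelCalibration | None = None,
    natural: NaturalAbundance | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render ground truth into noisy ion-count and filter tables.

    Expected atom fractions are natural abundance plus the forward-model
    excess plus the field's drift offset; each isotope channel is one
    Poisson draw with expectation (total element counts x fraction).  The
    filter table records each field's drifted outside-ROI fractions and an
    undrifted reference-filter record, so the drift correction can recover
    the true fractions exactly (up to counting noise).
    """
    rng = np.random.default_rng(rng)
    exp = exp or LabelingExperiment(mu_AOC=spec.mu_AOC)
    natural = natural or NaturalAbundance()
    cal = cal if cal is not None and cal.is_calibrated else calibrate(cal, exp, natural)

    xE13C, xE2H = forward_model(
        truth["mu_glc"].to_numpy(), truth["mu_ara"].to_numpy(), exp, cal, natural
    )

    fields = pd.unique(truth["field_id"])
    drift_C = dict(zip(fields, rng.normal(0.0, spec.drift_13C, size=fields.size)))
    drift_H = dict(zip(fields, rng.normal(0.0, spec.drift_2H, size=fields.size)))
    dC = truth["field_id"].map(drift_C).to_numpy()
    dH = truth["field_id"].map(drift_H).to_numpy()

    x13C = np.clip(natural.x13C + xE13C + dC, 0.0, 1.0)
    x2H = np.clip(natural.x2H + xE2H + dH, 0.0, 1.0)

    counts = truth[["replicate_id", "field_id", "roi_id"]].copy()
    counts["c1H"] = rng.poisson(spec.counts_H * (1.0 - x2H))
    counts["c2H"] = rng.poisson(spec.counts_H * x2H)
    counts["c12C"] = rng.poisson(spec.counts_C * (1.0 - x13C))
    counts["c13C"] = rng.poisson(spec.counts_C * x13C)

    filt_rows = [
        {
            "field_id": f,
            "x13C_filter": natural.x13C + drift_C[f],
            "x2H_filter": natural.x2H + drift_H[f],
            "is_reference": 0,
        }
        for f in fields
    ]
    filt_rows.append(
        {
            "field_id": "reference",
            "x13C_filter": natural.x13C,
            "x2H_filter": natural.x2H,
            "is_reference": 1,
        }
    )
    return counts, pd.DataFrame(filt_rows)


def render_fluorescence(
    truth: pd.DataFrame,
    spec: PopulationSpec,
    rng: np.random.Generator | int | None = None,
    intensity_scale: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render reporter fluorescence (gfp/mcherry) and its background table.

    Per cell, a shared lognormal global-expression factor multiplies both
    channels (raw GFP and mCherry are therefore positively correlated even
    without any specialization coupling), while the channel ratio shifts
    with the cell's true ``s`` by ``coupling``: mCherry (glucose reporter)
    rises and GFP (arabinose reporter) falls as ``s`` increases.  Additive
    per-field filter background and constant autofluorescence complete the
    raw intensities.
    """
    rng = np.random.default_rng(rng)
    n = len(truth)
    s = truth["s"].to_numpy()
    global_expr = rng.lognormal(0.0, spec.global_expression_sd, size=n)
    noise_g = rng.normal(0.0, spec.channel_noise_sd, size=n)
    noise_m = rng.normal(0.0, spec.channel_noise_sd, size=n)
    mcherry_sig = global_expr * np.exp(spec.coupling * s + noise_m)
    gfp_sig = global_expr * np.exp(-spec.coupling * s + noise_g)

    fields = pd.unique(truth["field_id"])
    bg = pd.DataFrame(
        {
            "field_id": fields,
            "bg_gfp": 20.0 + rng.normal(0.0, 2.0, size=fields.size),
            "bg_mcherry": 20.0 + rng.normal(0.0, 2.0, size=fields.size),
            "auto_gfp": 5.0,
            "auto_mcherry": 5.0,
        }
    )
    bg_map_g = dict(zip(bg["field_id"], bg["bg_gfp"]))
    bg_map_m = dict(zip(bg["field_id"], bg["bg_mcherry"]))
    fluor = truth[["replicate_id", "field_id", "roi_id"]].copy()
    fluor["gfp"] = (
        intensity_scale * gfp_sig + truth["field_id"].map(bg_map_g).to_numpy() + 5.0
    )
    fluor["mcherry"] = (
        intensity_scale * mcherry_sig + truth["field_id"].map(bg_map_m).to_numpy() + 5.0
    )
    return fluor, bg


def simulate_experiment(
    spec: PopulationSpec,
    exp: LabelingExperiment | None = None,
    cal: LabelCalibration | None = None,
    natural: NaturalAbundance | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Full synthetic experiment: truth, counts, filters, fluorescence.

    Returns a dict with keys ``truth``, ``counts``, ``filters``,
    ``fluorescence`` (gfp/mcherry merged into the counts rows) and
    ``fluorescence_background``.  A single seeded generator drives all
    sampling, so identical seeds give identical tables.
    """
    rng = np.random.default_rng(seed)
    exp = exp or LabelingExperiment(mu_AOC=spec.mu_AOC)
    truth = sample_population(spec, rng)
    counts, filters = render_counts(truth, spec, exp, cal, natural, rng)
    fluor, fluor_bg = render_fluorescence(truth, spec, rng)
    counts = counts.merge(
        fluor[["roi_id", "gfp", "mcherry"]], on="roi_id", validate="one_to_one"
    )
    return {
        "truth": truth,
        "counts": counts,
        "filters": filters,
        "fluorescence_background": fluor_bg,
    }
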