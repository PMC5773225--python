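"""Labeling-experiment constants, washout kinetics, and isotope-transfer calibration.

A dual-isotope labeling experiment supplies :sup:`13`\\ C-arabinose and
:sup:`2`\\ H-glucose to a culture for a fixed period.  In a chemostat the
unlabeled sugar pool washes out exponentially at the dilution rate after the
medium switch, so cells experience a time-averaged label purity below the
purity of the supplied sugars.  In batch mode the medium label fraction is
constant over the (short) labeling window.

Calibration experiments in which cells grow on a single labeled sugar for
many generations pin down how much of new-biomass carbon (respectively
hydrogen) is drawn from the sugar pathway; the remainder comes from
assimilable organic carbon (AOC) and, for hydrogen, exchange with water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "NaturalAbundance",
    "LabelingExperiment",
    "LabelCalibration",
    "unlabeled_fraction",
    "mean_unlabeled_fraction",
    "calibrate",
    "doubling_time",
    "volume_change_time",
    "label_period_fractions",
    "new_biomass_fraction",
]

#: Default natural atom fractions of unlabeled biomass.
X13C_NATURAL = 0.009928
X2H_NATURAL = 0.0002642


@dataclass(frozen=True)
class NaturalAbundance:
    """Isotopic composition of unlabeled biomass (atom fractions)."""

    x13C: float = X13C_NATURAL
    x2H: float = X2H_NATURAL

    def __post_init__(self) -> None:
        for name, v in (("x13C", self.x13C), ("x2H", self.x2H)):
            if not 0.0 < v < 0.05:
                raise ValueError(
                    f"natural abundance {name}={v} outside the plausible range (0, 0.05)"
                )


@dataclass(frozen=True)
class LabelingExperiment:
    """Culture and labeling constants for one experiment.

    Parameters
    ----------
    mode
        ``"chemostat"`` (continuous culture; unlabeled sugars wash out at the
        dilution rate after the medium switch) or ``"batch"`` (constant medium
        label fraction).
    D
        Dilution rate in 1/h.  At steady state this equals the population
        growth rate.
    T_label
        Duration of the stable-isotope incubation in hours.
    V, F
        Culture volume (ml) and medium pump rate (ml/h); ``D`` must equal
        ``F/V`` when all three are given for a chemostat.
    p_ara, p_glc
        Isotopic purity of the supplied 13C-arabinose and 2H-glucose.
    batch_label_fraction
        Fraction of the medium sugar pool that is labeled in batch mode.
    mu_AOC
        Growth rate supported by assimilable organic carbon, shared by all
        cells (1/h).
    mu_max
        Maximum specific growth rate of the strain (1/h); used only to cap
        the inversion search interval.
    supply_glc, supply_ara
        Sugar concentrations in the feed (same units for both; defaults are
        the 10 uM of carbon-limited medium).  Used to availability-normalize
        the specialization index.
    """

    mode: str = "chemostat"
    D: float = 0.15
    T_label: float = 3.0
    V: float = 5.6
    F: float = 0.84
    p_ara: float = 0.99
    p_glc: float = 0.97
    batch_label_fraction: float = 0.5
    mu_AOC: float = 0.010
    mu_max: float = 0.575
    supply_glc: float = 10.0
    supply_ara: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("chemostat", "batch"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "chemostat":
            if self.D <= 0:
                raise ValueError("chemostat dilution rate D must be positive")
            if self.V and self.F and abs(self.D - self.F / self.V) / self.D >= 1e-6:
                raise ValueError(
                    f"inconsistent chemostat constants: D={self.D} but F/V="
                    f"{self.F / self.V}"
                )
        for name in ("p_ara", "p_glc"):
            p = getattr(self, name)
            if not 0.0 < p <= 1.0:
                raise ValueError(f"{name}={p} must be in (0, 1]")
        if not 0.0 < self.batch_label_fraction <= 1.0:
            raise ValueError("batch_label_fraction must be in (0, 1]")
        if self.T_label <= 0:
            raise ValueError("T_label must be positive")
        if self.mu_AOC < 0:
            raise ValueError("mu_AOC must be non-negative")

    def mean_unlabeled_fraction(self) -> float:
        """Labeling-period average of the unlabeled fraction of medium sugar."""
        if self.mode == "batch":
            return 1.0 - self.batch_label_fraction
        return mean_unlabeled_fraction(self.D, self.T_label)

    def mean_purity(self, p_supplied: float, x_natural: float) -> float:
        """Washout-averaged heavy-isotope fraction of one medium sugar.

        Mixture of supplied labeled sugar (purity ``p_supplied``) and the
        residual unlabeled pool (natural abundance ``x_natural``).
        """
        u = self.mean_unlabeled_fraction()
        return (1.0 - u) * p_supplied + u * x_natural


def unlabeled_fraction(D: float, t: float) -> float:
    """Fraction of the sugar pool still unlabeled ``t`` hours after the switch.

    The unlabeled pool in a chemostat decays as ``exp(-D*t)`` once the inflow
    carries labeled sugar.
    """
    if D <= 0:
        raise ValueError("dilution rate D must be positive")
    if t < 0:
        raise ValueError("time t must be non-negative")
    return math.exp(-D * t)


def mean_unlabeled_fraction(D: float, T: float) -> float:
    """Time average of :func:`unlabeled_fraction` over the labeling period.

    Closed form of ``(1/T) * integral_0^T exp(-D t) dt``::

        (1 - exp(-D*T)) / (D*T)
    """
    if D <= 0 or T <= 0:
        raise ValueError("D and T must be positive")
    return -math.expm1(-D * T) / (D * T)


@dataclass(frozen=True)
class LabelCalibration:
    """Transfer coefficients linking sugar assimilation to biomass enrichment.

    ``kappa_C`` is the fraction of newly made biomass carbon drawn from the
    assimilated sugar when growing on that sugar alone (the rest coming from
    AOC); ``eta_H`` is the analogous fraction of new-biomass hydrogen drawn
    from glucose (the rest from AOC and exchange with water).  Both are fixed
    by single-substrate calibration experiments: after >= 10 generations on a
    single labeled sugar essentially all biomass is newly formed and the
    population enrichment plateaus at ``x_max``.

    ``x13C_max`` / ``x2H_max`` are those measured asymptotic atom fractions
    (about 0.70 for carbon on labeled arabinose and 0.14 for hydrogen on
    labeled glucose).
    """

    x13C_max: float = 0.70
    x2H_max: float = 0.14
    kappa_C: float | None = None
    eta_H: float | None = None

    def __post_init__(self) -> None:
        for name in ("kappa_C", "eta_H"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} must be in (0, 1]")

    @property
    def is_calibrated(self) -> bool:
        return self.kappa_C is not None and self.eta_H is not None


def calibrate(
    cal: LabelCalibration | None = None,
    exp: LabelingExperiment | None = None,
    natural: NaturalAbundance | None = None,
) -> LabelCalibration:
    """Solve the single-substrate asymptotes for the transfer coefficients.

    After >= 10 generations on one labeled sugar the pre-label biomass term is
    negligible, so the plateau enrichment satisfies::

        x_max = x_natural + coeff * (p_supplied - x_natural)

    giving ``kappa_C = (x13C_max - x13C_nat) / (p_ara - x13C_nat)`` and
    ``eta_H = (x2H_max - x2H_nat) / (p_glc - x2H_nat)``.  Under the default
    constants these evaluate to about 0.704 and 0.144.
    """
    cal = cal or LabelCalibration()
    exp = exp or LabelingExperiment()
    natural = natural or NaturalAbundance()
    if cal.x13C_max <= natural.x13C:
        raise ValueError(
            f"x13C_max={cal.x13C_max} does not exceed natural abundance "
            f"{natural.x13C}: calibration impossible"
        )
    if cal.x2H_max <= natural.x2H:
        raise ValueError(
            f"x2H_max={cal.x2H_max} does not exceed natural abundance "
            f"{natural.x2H}: calibration impossible"
        )
    kappa_C = (cal.x13C_max - natural.x13C) / (exp.p_ara - natural.x13C)
    eta_H = (cal.x2H_max - natural.x2H) / (exp.p_glc - natural.x2H)
    return replace(cal, kappa_C=kappa_C, eta_H=eta_H)


def doubling_time(D: float) -> float:
    """Population doubling (generation) time ``ln(2)/D`` in hours."""
    if D <= 0:
        raise ValueError("D must be positive")
    return math.log(2.0) / D


def volume_change_time(V: float, F: float) -> float:
    """Time for one culture-volume change ``V/F`` in hours."""
    if V <= 0 or F <= 0:
        raise ValueError("V and F must be positive")
    return V / F


def label_period_fractions(T: float, exp: LabelingExperiment) -> tuple[float, float]:
    """Labeling period as (% of one volume change, % of one generation time)."""
    if T <= 0:
        raise ValueError("T must be positive")
    return (
        T / volume_change_time(exp.V, exp.F) * 100.0,
        T / doubling_time(exp.D) * 100.0,
    )


def new_biomass_fraction(n_generations: float) -> float:
    """Fraction of biomass newly formed after ``n`` generations: ``1 - 2**-n``."""
    if n_generations < 0:
        raise ValueError("number of generations must be non-negative")
    return 1.0 - 2.0 ** (-n_generations)
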