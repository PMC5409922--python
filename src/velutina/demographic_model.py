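"""Density-dependent colony dynamics with layered imperfect detection.

The number of colonies (equivalently primary nests) founded in year ``y`` is

    P_y ~ Poisson( r * S_{y-1} / (1 + S_{y-1} / kappa) )

where ``S_{y-1}`` is the number of *successful* secondary nests the year
before — secondaries not destroyed while active, hence assumed to have
released hibernating foundresses.  ``r`` is the intrinsic between-year growth
rate and ``kappa`` scales the density dependence (a Beverton-Holt-type
saturating mean, bounded above by ``r * kappa``).

Detection, and for active nests destruction, is binomial thinning in three
layers: active primaries (probability ``d_AP``), then active secondaries
among the survivors (``d_AS``), then inactive secondaries among the
successful colonies (``d_IS``, with no demographic effect — those colonies
already released foundresses).  Each probability follows its own
logit-linear-in-time schedule.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "DetectionSchedule",
    "ModelParams",
    "CohortSlice",
    "mean_primaries",
    "step_cohort",
    "equilibrium_no_control",
    "equilibrium_with_control",
    "expected_discoveries",
]


@dataclass(frozen=True)
class DetectionSchedule:
    """Per-year detection probability, linear in time on the logit scale.

    ``probability(t) = expit(logit_intercept + logit_slope * t)`` with
    ``t = 0`` at the first observed year.  The logit-linear form keeps the
    probability inside (0, 1) for every year without clipping.
    """

    logit_intercept: float
    logit_slope: float = 0.0

    def probability(self, year_index: Union[int, np.ndarray]) -> Union[float, np.ndarray]:
        return expit(self.logit_intercept + self.logit_slope * np.asarray(year_index, float))

    @classmethod
    def constant(cls, p: float) -> "DetectionSchedule":
        return cls(logit_intercept=float(logit(p)), logit_slope=0.0)

    @classmethod
    def from_probabilities(cls, p_first: float, p_last: float, n_years: int) -> "DetectionSchedule":
        """Schedule passing through ``p_first`` at t=0 and ``p_last`` at t=n_years-1."""
        if n_years < 2:
            raise ValueError("need at least two years to set a slope")
        a = float(logit(p_first))
        b = (float(logit(p_last)) - a) / (n_years - 1)
        return cls(logit_intercept=a, logit_slope=b)


@dataclass(frozen=True)
class ModelParams:
    """Demographic parameters and the three detection schedules."""

    r: float
    kappa: float
    det_active_primary: DetectionSchedule
    det_active_secondary: DetectionSchedule
    det_inactive_secondary: DetectionSchedule

    def __post_init__(self) -> None:
        if self.r <= 0 or self.kappa <= 0:
            raise ValueError("r and kappa must be positive")


def mean_primaries(S_prev: float, r: float, kappa: float) -> float:
    """Expected primaries next year given ``S_prev`` successful secondaries.

    ``r * S / (1 + S / kappa)``: increasing and concave in ``S``, saturating
    at ``r * kappa``.
    """
    if S_prev < 0 or r < 0 or kappa <= 0:
        raise ValueError("mean_primaries requires S_prev, r >= 0 and kappa > 0")
    return r * S_prev / (1.0 + S_prev / kappa)


@dataclass(frozen=True)
class CohortSlice:
    """One year of the latent process plus its observed counts.

    Every colony of the cohort ends up in exactly one of: destroyed as an
    active primary (``n_active_primary_destroyed``), destroyed as an active
    secondary (``n_active_secondary_destroyed``), or successful
    (``n_successful``).  ``n_inactive_secondary_detected`` nests are detected
    among the successful colonies without demographic effect.
    """

    year_index: int
    n_primaries: int
    n_active_primary_destroyed: int
    n_active_secondary_destroyed: int
    n_successful: int
    n_inactive_secondary_detected: int

    @property
    def observed(self) -> tuple[int, int, int]:
        """(active primaries, active secondaries, inactive secondaries) seen."""
        return (
            self.n_active_primary_destroyed,
            self.n_active_secondary_destroyed,
            self.n_inactive_secondary_detected,
        )


def step_cohort(
    S_prev: int,
    params: ModelParams,
    year_index: int,
    rng: np.random.Generator,
) -> CohortSlice:
    """Simulate one year: Poisson reproduction then three binomial thinnings."""
    if S_prev < 0:
        raise ValueError("S_prev must be non-negative")
    mu = mean_primaries(S_prev, params.r, params.kappa)
    P = int(rng.poisson(mu))
    d_ap = float(params.det_active_primary.probability(year_index))
    d_as = float(params.det_active_secondary.probability(year_index))
    d_is = float(params.det_inactive_secondary.probability(year_index))
    A_P = int(rng.binomial(P, d_ap)) if P else 0
    survivors = P - A_P
    A_S = int(rng.binomial(survivors, d_as)) if survivors else 0
    S = survivors - A_S
    I_S = int(rng.binomial(S, d_is)) if S else 0
    return CohortSlice(
        year_index=year_index,
        n_primaries=P,
        n_active_primary_destroyed=A_P,
        n_active_secondary_destroyed=A_S,
        n_successful=S,
        n_inactive_secondary_detected=I_S,
    )


def equilibrium_no_control(r: float, kappa: float) -> float:
    """Deterministic carrying capacity of colonies without any destruction.

    The non-zero fixed point of ``S -> mean_primaries(S)`` with every colony
    succeeding (S = P), namely ``kappa * (r - 1)`` when ``r > 1``; a
    population at or below replacement (``r <= 1``) equilibrates at 0.
    """
    if r <= 0 or kappa <= 0:
        raise ValueError("r and kappa must be positive")
    return kappa * (r - 1.0) if r > 1.0 else 0.0


def equilibrium_with_control(params: ModelParams, year_index: int) -> tuple[float, float]:
    """(colonies P*, successful secondaries S*) at equilibrium under control.

    With per-colony survival ``q = (1 - d_AP)(1 - d_AS)`` at the given year's
    detection levels, the successful-secondary fixed point solves
    ``S = q * mean_primaries(S)``: ``S* = kappa (r q - 1)`` when ``r q > 1``,
    else 0 (control drives the population extinct); ``P* = S*/q``.
    """
    d_ap = float(params.det_active_primary.probability(year_index))
    d_as = float(params.det_active_secondary.probability(year_index))
    q = (1.0 - d_ap) * (1.0 - d_as)
    if params.r * q <= 1.0:
        return 0.0, 0.0
    S_star = params.kappa * (params.r * q - 1.0)
    return S_star / q, S_star


def expected_discoveries(
    P_star: float,
    S_star: float,
    params: ModelParams,
    year_index: int,
) -> tuple[float, float, float]:
    """Expected annual discoveries at equilibrium.

    Returns (active primaries, active secondaries, inactive secondaries):
    ``(P* d_AP, P*(1 - d_AP) d_AS, S* d_IS)``.
    """
    if P_star < 0 or S_star < 0:
        raise ValueError("equilibrium abundances must be non-negative")
    d_ap = float(params.det_active_primary.probability(year_index))
    d_as = float(params.det_active_secondary.probability(year_index))
    d_is = float(params.det_inactive_secondary.probability(year_index))
    return (P_star * d_ap, P_star * (1.0 - d_ap) * d_as, S_star * d_is)
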