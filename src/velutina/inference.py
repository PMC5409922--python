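"""Bayesian inference of the colony-dynamics model by Metropolis-Hastings.

The observed data are yearly counts of destroyed active primaries, destroyed
active secondaries and detected inactive secondaries (plus, for years in
which nest stage was never recorded, only a detected-colony total).  The
latent state is the true number of colonies founded each year, ``P_y``, plus
the number of successful secondaries the year before observation began,
``S_init``.  Conditional on the latents the likelihood factorises into one
Poisson reproduction term and three binomial detection terms per year.

The sampler is a block-wise random-walk Metropolis-Hastings: Gaussian
proposals for the continuous parameters (log r, log kappa, the six
logit-schedule coefficients) — both one at a time and jointly along an
empirical covariance adapted during burn-in, which is what lets the chain
traverse the strong r-kappa ridge — and symmetric integer steps for
``S_init`` and each ``P_y``.  The inner loop is compiled with numba.

Derived predictions (carrying capacities with and without control, expected
annual discoveries, discovery percentages) are always computed per posterior
sample and then summarised, never from summarised parameters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import log
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit

from .demographic_model import DetectionSchedule, ModelParams
from .nest_records import YearlyCounts, detected_colonies

__all__ = [
    "CountData",
    "PriorSpec",
    "MCMCConfig",
    "LatentState",
    "PosteriorChain",
    "log_likelihood",
    "log_posterior",
    "run_mcmc",
    "summarize_posterior",
    "summarize_samples",
    "credible_interval",
    "discovery_percentages",
    "diagnostics",
]

_PARAM_NAMES = (
    "log_r", "log_kappa",
    "ap_intercept", "ap_slope",
    "as_intercept", "as_slope",
    "is_intercept", "is_slope",
)


@dataclass(frozen=True)
class CountData:
    """Observed yearly counts arranged for the likelihood.

    For ``stage_known`` years the three class counts are used; for the others
    only the detected-colony total enters (as a single binomial with the
    active-secondary detection probability) and ``removed_unclassified``
    gives the nests of that year destroyed while active, which reduce the
    successful-secondary count.
    """

    years: np.ndarray
    stage_known: np.ndarray          # bool
    colonies: np.ndarray             # detected colonies
    active_primary: np.ndarray       # A_P (0 where stage unknown)
    active_secondary: np.ndarray     # A_S
    inactive_secondary: np.ndarray   # I_S
    removed_unclassified: np.ndarray

    @classmethod
    def from_yearly_counts(cls, counts: Sequence[YearlyCounts]) -> "CountData":
        counts = sorted(counts, key=lambda c: c.year)
        years = np.array([c.year for c in counts])
        if len(years) and np.any(np.diff(years) != 1):
            raise ValueError("years must be consecutive")
        return cls(
            years=years,
            stage_known=np.array([c.stage_recorded for c in counts]),
            colonies=np.array([detected_colonies(c) for c in counts]),
            active_primary=np.array([c.n_active_primary_destroyed for c in counts]),
            active_secondary=np.array([c.n_active_secondary_destroyed for c in counts]),
            inactive_secondary=np.array([c.n_inactive_secondary_detected for c in counts]),
            removed_unclassified=np.array(
                [c.n_active_unclassified_destroyed for c in counts]
            ),
        )

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def min_primaries(self) -> np.ndarray:
        """Smallest latent P_y consistent with each year's observations."""
        known = (
            self.active_primary + self.active_secondary + self.inactive_secondary
        )
        unknown = np.maximum(self.colonies, self.removed_unclassified)
        return np.where(self.stage_known, known, unknown)

    def _packed(self):
        """(k_mask, ap, as_, is_, colonies, removed, t) as float/bool arrays."""
        removed = np.where(
            self.stage_known,
            self.active_primary + self.active_secondary,
            self.removed_unclassified,
        ).astype(np.float64)
        return (
            self.stage_known.astype(np.bool_),
            self.active_primary.astype(np.float64),
            self.active_secondary.astype(np.float64),
            self.inactive_secondary.astype(np.float64),
            self.colonies.astype(np.float64),
            removed,
            np.arange(self.n_years, dtype=np.float64),
        )


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative default priors (the study reports none).

    ``r`` and ``kappa`` are log-normal (median 5 and 50, broad); schedule
    coefficients are normal on the logit scale; ``S_init`` is discrete
    uniform on 1..``s_init_max``.
    """

    r_log_median: float = log(5.0)
    r_log_sd: float = 1.0
    kappa_log_median: float = log(50.0)
    kappa_log_sd: float = 1.5
    intercept_sd: float = 2.0
    slope_sd: float = 0.5
    s_init_max: int = 20

    def _packed(self):
        means = np.array([
            self.r_log_median, self.kappa_log_median, 0, 0, 0, 0, 0, 0
        ])
        sds = np.array([
            self.r_log_sd, self.kappa_log_sd,
            self.intercept_sd, self.slope_sd,
            self.intercept_sd, self.slope_sd,
            self.intercept_sd, self.slope_sd,
        ])
        return means, sds, int(self.s_init_max)


@dataclass(frozen=True)
class MCMCConfig:
    n_iterations: int = 200_000
    n_burn_in: int = 40_000
    thinning: int = 20
    n_chains: int = 4
    seed: int = 0
    #: initial Gaussian proposal sd per continuous parameter
    proposal_scales: Mapping[str, float] = field(
        default_factory=lambda: {
            "log_r": 0.10, "log_kappa": 0.30,
            "ap_intercept": 0.30, "ap_slope": 0.10,
            "as_intercept": 0.30, "as_slope": 0.10,
            "is_intercept": 0.30, "is_slope": 0.10,
        }
    )
    latent_step: int = 5     # P_y proposals: uniform on +-1..latent_step
    global_step: int = 12    # whole-trajectory shift proposals: +-1..global_step
    s_init_step: int = 2
    adapt: bool = True       # tune proposal scales toward ~25% during burn-in

    def __post_init__(self) -> None:
        if not 0 <= self.n_burn_in < self.n_iterations:
            raise ValueError("need 0 <= n_burn_in < n_iterations")
        if self.thinning < 1 or self.n_chains < 1:
            raise ValueError("thinning and n_chains must be >= 1")


@dataclass(frozen=True)
class LatentState:
    """Latent trajectory: colonies per year and the pre-study seed count."""

    primaries: np.ndarray  # P_y, integers, aligned with CountData.years
    s_init: int


@njit(cache=True)
def _binom_term(k: float, n: float, p: float) -> float:
    """log Binomial(k; n, p) for 0 <= k <= n, any p in [0, 1]."""
    if k < 0.0 or k > n:
        return -np.inf
    if p <= 0.0:
        return 0.0 if k == 0.0 else -np.inf
    if p >= 1.0:
        return 0.0 if k == n else -np.inf
    return (
        math.lgamma(n + 1.0) - math.lgamma(k + 1.0) - math.lgamma(n - k + 1.0)
        + k * math.log(p) + (n - k) * math.log1p(-p)
    )


@njit(cache=True)
def _detection(a: float, b: float, t: float, linear: bool) -> float:
    """Detection probability at year index t (logit-linear or clipped linear)."""
    if linear:
        d = a + b * t
        if d < 1e-12:
            return 1e-12
        if d > 1.0 - 1e-12:
            return 1.0 - 1e-12
        return d
    return 1.0 / (1.0 + math.exp(-(a + b * t)))


@njit(cache=True)
def _nb_loglik(theta, s_init, P, k_mask, ap, as_, is_, colonies, removed, t, linear_det):
    n = P.shape[0]
    r = math.exp(theta[0])
    kappa = math.exp(theta[1])
    ll = 0.0
    S_prev = float(s_init)
    for y in range(n):
        Py = float(P[y])
        S = Py - removed[y]
        if S < 0.0:
            return -np.inf
        mu = r * S_prev / (1.0 + S_prev / kappa)
        if mu <= 0.0:
            if Py > 0.0:
                return -np.inf
        else:
            ll += Py * math.log(mu) - mu - math.lgamma(Py + 1.0)
        if k_mask[y]:
            d1 = _detection(theta[2], theta[3], t[y], linear_det)
            d2 = _detection(theta[4], theta[5], t[y], linear_det)
            d3 = _detection(theta[6], theta[7], t[y], linear_det)
            surv = Py - ap[y]
            ll += _binom_term(ap[y], Py, d1)
            ll += _binom_term(as_[y], surv, d2)
            ll += _binom_term(is_[y], S, d3)
        else:
            # colony-count years: a colony is detected if its (secondary)
            # nest is found while active or later while inactive
            d2 = _detection(theta[4], theta[5], t[y], linear_det)
            d3 = _detection(theta[6], theta[7], t[y], linear_det)
            ll += _binom_term(colonies[y], Py, d2 + (1.0 - d2) * d3)
        if not np.isfinite(ll):
            return -np.inf
        S_prev = S
    return ll


@njit(cache=True)
def _nb_prior(theta, s_init, means, sds, s_init_max):
    if s_init < 1 or s_init > s_init_max:
        return -np.inf
    lp = -math.log(s_init_max)
    for j in range(theta.shape[0]):
        z = (theta[j] - means[j]) / sds[j]
        lp += -0.5 * z * z - math.log(sds[j]) - 0.9189385332046727  # log sqrt(2 pi)
    return lp


@njit(cache=True)
def _nb_chain(
    seed, n_iter, burn, thin, keep,
    k_mask, ap, as_, is_, colonies, removed, t,
    means, sds, s_init_max,
    theta0, s_init0, P0,
    scales0, latent_step, global_step, s_init_step, adapt, joint_start,
    linear_det,
):
    """One MCMC chain; returns stored samples and per-block acceptance counts."""
    np.random.seed(seed)
    n_par = theta0.shape[0]
    n_years = P0.shape[0]
    theta = theta0.copy()
    s_init = s_init0
    P = P0.astype(np.float64)
    scales = scales0.copy()

    lp = _nb_prior(theta, s_init, means, sds, s_init_max) + _nb_loglik(
        theta, s_init, P, k_mask, ap, as_, is_, colonies, removed, t, linear_det
    )

    theta_store = np.empty((keep, n_par))
    s_store = np.empty(keep, dtype=np.int64)
    P_store = np.empty((keep, n_years), dtype=np.int64)
    lp_store = np.empty(keep)
    acc = np.zeros(n_par + 3 + n_years)
    history = np.empty((burn, n_par))
    chol = np.zeros((n_par, n_par))
    have_chol = False
    joint_scale = 2.38 / math.sqrt(n_par)
    acc_win = np.zeros(n_par)
    acc_joint_win = 0.0
    n_win = 0
    kept = 0

    for it in range(n_iter):
        # single-site continuous updates
        for j in range(n_par):
            old = theta[j]
            theta[j] = old + np.random.normal() * scales[j]
            lp2 = _nb_prior(theta, s_init, means, sds, s_init_max)
            if np.isfinite(lp2):
                lp2 += _nb_loglik(theta, s_init, P, k_mask, ap, as_, is_, colonies, removed, t, linear_det)
            if math.log(np.random.random()) < lp2 - lp:
                lp = lp2
                acc_win[j] += 1.0
                if it >= burn:
                    acc[j] += 1.0
            else:
                theta[j] = old
        # joint continuous update along adapted covariance
        if have_chol:
            z = np.empty(n_par)
            for j in range(n_par):
                z[j] = np.random.normal()
            prop = theta + joint_scale * (chol @ z)
            lp2 = _nb_prior(prop, s_init, means, sds, s_init_max)
            if np.isfinite(lp2):
                lp2 += _nb_loglik(prop, s_init, P, k_mask, ap, as_, is_, colonies, removed, t, linear_det)
            if math.log(np.random.random()) < lp2 - lp:
                theta = prop
                lp = lp2
                acc_joint_win += 1.0
                if it >= burn:
                    acc[n_par] += 1.0
        n_win += 1
        # pre-study seed count
        step = np.random.randint(1, s_init_step + 1)
        if np.random.random() < 0.5:
            step = -step
        s2 = s_init + step
        lp2 = _nb_prior(theta, s2, means, sds, s_init_max)
        if np.isfinite(lp2):
            lp2 += _nb_loglik(theta, s2, P, k_mask, ap, as_, is_, colonies, removed, t, linear_det)
        if math.log(np.random.random()) < lp2 - lp:
            s_init = s2
            lp = lp2
            if it >= burn:
                acc[n_par + 1] += 1.0
        # latent colonies, year by year
        for y in range(n_years):
            step = np.random.randint(1, latent_step + 1)
            if np.random.random() < 0.5:
                step = -step
            old_p = P[y]
            P[y] = old_p + step
            if P[y] < 0.0:
                P[y] = old_p
                continue
            lp2 = _nb_prior(theta, s_init, means, sds, s_init_max) + _nb_loglik(
                theta, s_init, P, k_mask, ap, as_, is_, colonies, removed, t, linear_det
            )
            if math.log(np.random.random()) < lp2 - lp:
                lp = lp2
                if it >= burn:
                    acc[n_par + 3 + y] += 1.0
            else:
                P[y] = old_p
        # whole-trajectory shift: moves the overall population level, which
        # is strongly coupled to the detection intercepts
        step = np.random.randint(1, global_step + 1)
        if np.random.random() < 0.5:
            step = -step
        P2 = P + step
        ok = True
        for y in range(n_years):
            if P2[y] < 0.0:
                ok = False
                break
        if ok:
            lp2 = _nb_prior(theta, s_init, means, sds, s_init_max) + _nb_loglik(
                theta, s_init, P2, k_mask, ap, as_, is_, colonies, removed, t, linear_det
            )
            if math.log(np.random.random()) < lp2 - lp:
                P = P2
                lp = lp2
                if it >= burn:
                    acc[n_par + 2] += 1.0

        if it < burn:
            for j in range(n_par):
                history[it, j] = theta[j]
            if adapt and n_win == 50:
                for j in range(n_par):
                    scales[j] *= math.exp(0.6 * (acc_win[j] / n_win - 0.25))
                    if scales[j] < 1e-3:
                        scales[j] = 1e-3
                    elif scales[j] > 5.0:
                        scales[j] = 5.0
                if have_chol:
                    joint_scale *= math.exp(0.6 * (acc_joint_win / n_win - 0.25))
                    lo_js = 0.02 * 2.38 / math.sqrt(n_par)
                    hi_js = 20.0 * 2.38 / math.sqrt(n_par)
                    if joint_scale < lo_js:
                        joint_scale = lo_js
                    elif joint_scale > hi_js:
                        joint_scale = hi_js
                acc_win[:] = 0.0
                acc_joint_win = 0.0
                n_win = 0
            if it + 1 >= joint_start and (it + 1 - joint_start) % 500 == 0:
                lo = (it + 1) // 2
                m = it + 1 - lo
                if m > 10 * n_par:
                    seg = history[lo:it + 1]
                    mean = np.zeros(n_par)
                    for i in range(m):
                        mean += seg[i]
                    mean /= m
                    cov = np.zeros((n_par, n_par))
                    for i in range(m):
                        dev = seg[i] - mean
                        cov += np.outer(dev, dev)
                    cov /= m - 1
                    for j in range(n_par):
                        cov[j, j] += 1e-8
                    chol = np.linalg.cholesky(cov)
                    have_chol = True

        if it >= burn and (it - burn) % thin == 0 and kept < keep:
            for j in range(n_par):
                theta_store[kept, j] = theta[j]
            s_store[kept] = s_init
            for y in range(n_years):
                P_store[kept, y] = int(P[y])
            lp_store[kept] = lp
            kept += 1

    return theta_store, s_store, P_store, lp_store, acc


def _theta_from_params(params: ModelParams) -> np.ndarray:
    return np.array([
        log(params.r), log(params.kappa),
        params.det_active_primary.logit_intercept, params.det_active_primary.logit_slope,
        params.det_active_secondary.logit_intercept, params.det_active_secondary.logit_slope,
        params.det_inactive_secondary.logit_intercept, params.det_inactive_secondary.logit_slope,
    ])


def log_likelihood(params: ModelParams, latents: LatentState, data: CountData) -> float:
    """Log-likelihood of the observed counts given parameters and latents.

    Sum over years of the Poisson reproduction term and the binomial
    detection terms; any observed count exceeding its latent denominator
    yields ``-inf`` (an impossible configuration), never an exception.
    """
    P = np.asarray(latents.primaries, dtype=np.float64)
    if P.shape != data.years.shape:
        raise ValueError("latent primaries must align with the data years")
    k_mask, ap, as_, is_, colonies, removed, t = data._packed()
    return float(_nb_loglik(
        _theta_from_params(params), int(latents.s_init), P,
        k_mask, ap, as_, is_, colonies, removed, t, False,
    ))


def log_posterior(
    params: ModelParams,
    latents: LatentState,
    data: CountData,
    priors: Optional[PriorSpec] = None,
) -> float:
    """Log posterior density: likelihood plus prior log-densities (-inf propagates)."""
    priors = priors or PriorSpec()
    means, sds, s_max = priors._packed()
    lp = float(_nb_prior(_theta_from_params(params), int(latents.s_init), means, sds, s_max))
    if np.isneginf(lp):
        return -np.inf
    return lp + log_likelihood(params, latents, data)


@dataclass
class PosteriorChain:
    """Thinned post-burn-in MCMC samples plus per-block acceptance rates.

    Scalar entries of ``samples`` have shape (n_chains, n_draws); the latent
    trajectory ``"P"`` has shape (n_chains, n_draws, n_years).
    """

    samples: dict[str, np.ndarray]
    years: np.ndarray
    acceptance: dict[str, float]
    config: MCMCConfig
    priors: PriorSpec
    detection_form: str = "logit"

    def _prob(self, prefix: str, t: float) -> np.ndarray:
        a = self.flat(f"{prefix}_intercept")
        b = self.flat(f"{prefix}_slope")
        if self.detection_form == "linear":
            return np.clip(a + b * t, 1e-12, 1 - 1e-12)
        return expit(a + b * t)

    @property
    def n_chains(self) -> int:
        return self.samples["r"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.samples["r"].shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All chains concatenated (draws first axis)."""
        x = self.samples[name]
        return x.reshape(-1, *x.shape[2:])

    def max_year_index(self) -> int:
        return len(self.years) - 1

    def derived(self, year_index: Optional[int] = None) -> dict[str, np.ndarray]:
        """Per-sample derived quantities at the given detection year.

        Defaults to the final observed year ("maximum detection").  All
        quantities are computed sample-wise so that posterior summaries of
        nonlinear functions are honest.
        """
        tmax = self.max_year_index() if year_index is None else year_index
        r = self.flat("r")
        kappa = self.flat("kappa")
        d_ap = self._prob("ap", tmax)
        d_as = self._prob("as", tmax)
        d_is = self._prob("is", tmax)
        K_nc = np.where(r > 1, kappa * (r - 1), 0.0)
        q = (1 - d_ap) * (1 - d_as)
        S_star = np.where(r * q > 1, kappa * (r * q - 1), 0.0)
        P_star = np.where(S_star > 0, S_star / q, 0.0)
        e_ap = P_star * d_ap
        e_as = P_star * (1 - d_ap) * d_as
        e_is = S_star * d_is
        # Per-colony discovery probabilities: each colony is discovered at
        # most once in this accounting (as an active primary, else as an
        # active secondary, else possibly as an inactive secondary).
        p_active = d_ap + (1 - d_ap) * d_as
        p_ever = p_active + q * d_is
        total_nests = P_star * (2 - d_ap)  # one primary + one secondary per survivor
        with np.errstate(invalid="ignore", divide="ignore"):
            pct_nests = np.where(total_nests > 0, 100 * (e_ap + e_as + e_is) / total_nests, 0.0)
        return {
            "r": r,
            "kappa": kappa,
            "K_no_control": K_nc,
            "K_control": P_star,
            "S_star_control": S_star,
            "d_active_primary_max": d_ap,
            "d_active_secondary_max": d_as,
            "d_inactive_secondary_max": d_is,
            "E_discoveries_active_primary": e_ap,
            "E_discoveries_active_secondary": e_as,
            "E_discoveries_inactive_secondary": e_is,
            "pct_discovered_ever": 100 * p_ever,
            "pct_discovered_active": 100 * p_active,
            "pct_nests_discovered_alt": pct_nests,
        }

    def params_at(self, chain: int, draw: int) -> ModelParams:
        s = self.samples
        return ModelParams(
            r=float(s["r"][chain, draw]),
            kappa=float(s["kappa"][chain, draw]),
            det_active_primary=DetectionSchedule(
                float(s["ap_intercept"][chain, draw]), float(s["ap_slope"][chain, draw])
            ),
            det_active_secondary=DetectionSchedule(
                float(s["as_intercept"][chain, draw]), float(s["as_slope"][chain, draw])
            ),
            det_inactive_secondary=DetectionSchedule(
                float(s["is_intercept"][chain, draw]), float(s["is_slope"][chain, draw])
            ),
        )

    def to_inference_data(self):
        """ArviZ InferenceData view (scalars plus per-year latent colonies)."""
        import arviz as az

        post = {k: v for k, v in self.samples.items() if k != "P"}
        for j, year in enumerate(self.years):
            post[f"P_{year}"] = self.samples["P"][:, :, j]
        return az.from_dict(posterior=post)

    def to_frame(self) -> pd.DataFrame:
        """One row per retained sample (chain and draw indices included)."""
        n_c, n_d = self.n_chains, self.n_draws
        cols: dict[str, np.ndarray] = {
            "chain": np.repeat(np.arange(n_c), n_d),
            "draw": np.tile(np.arange(n_d), n_c),
        }
        for k, v in self.samples.items():
            if k == "P":
                for j, year in enumerate(self.years):
                    cols[f"P_{year}"] = v[:, :, j].reshape(-1)
            else:
                cols[k] = v.reshape(-1)
        return pd.DataFrame(cols)


def _initial_state(data: CountData, priors: PriorSpec, rng: np.random.Generator,
                   linear_det: bool = False):
    if linear_det:
        theta = np.array([log(5.0), log(50.0), 0.15, 0.0, 0.25, 0.0, 0.25, 0.0])
        theta = theta + rng.normal(0.0, 0.05, size=theta.size)
        theta[:2] += rng.normal(0.0, 0.2, size=2)
    else:
        theta = np.array([
            log(5.0), log(50.0),
            -1.5, 0.0,   # active primary detection ~ 0.18
            -1.0, 0.0,   # active secondary detection ~ 0.27
            -1.0, 0.0,   # inactive secondary detection ~ 0.27
        ])
        theta = theta + rng.normal(0.0, 0.2, size=theta.size)
    min_p = data.min_primaries
    P = np.maximum(min_p, (2 * np.maximum(data.colonies, 1)).astype(int))
    P = P + rng.integers(0, 5, size=P.size)
    s_init = int(rng.integers(1, min(priors.s_init_max, 10) + 1))
    return theta, s_init, P.astype(np.int64)


def run_mcmc(
    data: CountData,
    priors: Optional[PriorSpec] = None,
    config: Optional[MCMCConfig] = None,
    detection_form: str = "logit",
) -> PosteriorChain:
    """Block-wise random-walk Metropolis-Hastings over parameters and latents.

    Chains are seeded as ``config.seed + chain_index`` and are exactly
    reproducible.  Proposal scales (and, from mid-burn-in, a joint proposal
    covariance estimated from the chain history) are tuned toward ~25%
    acceptance during burn-in, then frozen.

    ``detection_form`` selects how the per-class detection probability varies
    over years: ``"logit"`` (default; linear on the logit scale, always inside
    (0, 1)) or ``"linear"`` (a sensitivity variant: linear on the raw
    probability scale, clipped to [0, 1], with the schedule coefficients then
    read as raw intercept/slope).
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    if detection_form not in ("logit", "linear"):
        raise ValueError("detection_form must be 'logit' or 'linear'")
    linear_det = detection_form == "linear"
    n_par = len(_PARAM_NAMES)
    n_years = data.n_years
    keep = (config.n_iterations - config.n_burn_in) // config.thinning
    if keep < 1:
        raise ValueError("configuration retains no samples")
    k_mask, ap, as_, is_, colonies, removed, t = data._packed()
    means, sds, s_max = priors._packed()
    scales0 = np.array([config.proposal_scales[name] for name in _PARAM_NAMES])
    joint_start = config.n_burn_in // 2 if config.n_burn_in >= 400 else config.n_iterations

    store = {
        name: np.empty((config.n_chains, keep))
        for name in ("r", "kappa", "ap_intercept", "ap_slope", "as_intercept",
                     "as_slope", "is_intercept", "is_slope", "S_init",
                     "log_posterior")
    }
    store["P"] = np.empty((config.n_chains, keep, n_years), dtype=int)
    acc_total = np.zeros(n_par + 3 + n_years)

    for chain in range(config.n_chains):
        rng = np.random.default_rng(config.seed + chain)
        found = False
        for _ in range(500):
            theta0, s_init0, P0 = _initial_state(data, priors, rng, linear_det)
            lp0 = _nb_prior(theta0, s_init0, means, sds, s_max)
            if np.isfinite(lp0):
                lp0 += _nb_loglik(
                    theta0, s_init0, P0.astype(np.float64),
                    k_mask, ap, as_, is_, colonies, removed, t, linear_det,
                )
            if np.isfinite(lp0):
                found = True
                break
        if not found:
            raise RuntimeError(
                "could not find a starting state with finite posterior; "
                "widen the initial state or check the data for impossible counts"
            )
        theta_s, s_s, P_s, lp_s, acc = _nb_chain(
            config.seed + chain, config.n_iterations, config.n_burn_in,
            config.thinning, keep,
            k_mask, ap, as_, is_, colonies, removed, t,
            means, sds, s_max,
            theta0, s_init0, P0,
            scales0, config.latent_step, config.global_step, config.s_init_step,
            config.adapt, joint_start, linear_det,
        )
        store["r"][chain] = np.exp(theta_s[:, 0])
        store["kappa"][chain] = np.exp(theta_s[:, 1])
        for j, name in enumerate(_PARAM_NAMES[2:], start=2):
            store[name][chain] = theta_s[:, j]
        store["S_init"][chain] = s_s
        store["log_posterior"][chain] = lp_s
        store["P"][chain] = P_s
        acc_total += acc

    denom = max((config.n_iterations - config.n_burn_in) * config.n_chains, 1)
    acceptance = {name: acc_total[j] / denom for j, name in enumerate(_PARAM_NAMES)}
    acceptance["joint"] = acc_total[n_par] / denom
    acceptance["S_init"] = acc_total[n_par + 1] / denom
    acceptance["P_shift"] = acc_total[n_par + 2] / denom
    for y in range(n_years):
        acceptance[f"P_{data.years[y]}"] = acc_total[n_par + 3 + y] / denom
    return PosteriorChain(
        samples=store, years=data.years.copy(), acceptance=acceptance,
        config=config, priors=priors, detection_form=detection_form,
    )


def credible_interval(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval from posterior draws."""
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(np.asarray(x, float), [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def summarize_samples(
    samples: Mapping[str, np.ndarray], level: float = 0.95
) -> pd.DataFrame:
    """Median, mean and equal-tailed interval for each sample array."""
    rows = []
    for name, x in samples.items():
        x = np.asarray(x, float).reshape(-1)
        if x.size == 0:
            raise ValueError(f"no samples for {name!r}")
        lo, hi = credible_interval(x, level)
        rows.append({
            "quantity": name,
            "median": float(np.median(x)),
            "mean": float(np.mean(x)),
            "ci_low": lo,
            "ci_high": hi,
        })
    return pd.DataFrame(rows).set_index("quantity")


def summarize_posterior(chain: PosteriorChain, level: float = 0.95) -> pd.DataFrame:
    """Posterior summary of parameters, latents and derived predictions.

    Point estimates are posterior medians (means reported alongside); derived
    quantities are evaluated per sample at the final observed year's
    detection levels before summarising.
    """
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    quantities: dict[str, np.ndarray] = dict(chain.derived())
    quantities["d_active_primary_first"] = chain._prob("ap", 0)
    quantities["d_active_secondary_first"] = chain._prob("as", 0)
    quantities["d_inactive_secondary_first"] = chain._prob("is", 0)
    quantities["S_init"] = chain.flat("S_init")
    for j, year in enumerate(chain.years):
        quantities[f"P_{year}"] = chain.flat("P")[:, j]
    return summarize_samples(quantities, level)


def discovery_percentages(chain: PosteriorChain, level: float = 0.95) -> pd.DataFrame:
    """Percent of colonies ever discovered, and discovered while active.

    Computed per posterior sample from the per-colony discovery probabilities
    at maximum (final-year) detection; the nest-count-denominator variant is
    included as an alternative.
    """
    d = chain.derived()
    return summarize_samples(
        {
            "pct_discovered_ever": d["pct_discovered_ever"],
            "pct_discovered_active": d["pct_discovered_active"],
            "pct_nests_discovered_alt": d["pct_nests_discovered_alt"],
        },
        level,
    )


def plot_traces(chain: PosteriorChain, path) -> None:
    """Trace and posterior-density plots for r and kappa (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 6))
    for row, name in enumerate(("r", "kappa")):
        for c in range(chain.n_chains):
            axes[row, 0].plot(chain.samples[name][c], lw=0.4, alpha=0.7)
        axes[row, 0].set_ylabel(name)
        axes[row, 1].hist(chain.flat(name), bins=60, density=True, color="grey")
        axes[row, 1].set_xlabel(name)
    axes[0, 0].set_title("trace (per chain)")
    axes[0, 1].set_title("posterior density")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def diagnostics(chain: PosteriorChain) -> pd.DataFrame:
    """Split-Rhat and effective sample size for every stored scalar."""
    import arviz as az

    idata = chain.to_inference_data()
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = [
        {"quantity": name, "rhat": float(rhat[name]), "ess": float(ess[name])}
        for name in rhat.data_vars
    ]
    return pd.DataFrame(rows).set_index("quantity")
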