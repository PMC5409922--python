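"""Likelihood correctness (vs. exhaustive enumeration), posterior machinery."""
from functools import lru_cache

import numpy as np
import pytest
from scipy.stats import binom, poisson

from velutina.demographic_model import DetectionSchedule, ModelParams, mean_primaries
from velutina.inference import (
    CountData,
    LatentState,
    MCMCConfig,
    PriorSpec,
    credible_interval,
    diagnostics,
    discovery_percentages,
    log_likelihood,
    log_posterior,
    run_mcmc,
    summarize_posterior,
    summarize_samples,
)
from velutina.nest_records import YearlyCounts


def const_params(r, kappa, d_ap, d_as, d_is):
    return ModelParams(
        r=r, kappa=kappa,
        det_active_primary=DetectionSchedule.constant(d_ap),
        det_active_secondary=DetectionSchedule.constant(d_as),
        det_inactive_secondary=DetectionSchedule.constant(d_is),
    )


def enumerate_observation_probability(params, s_init, data, pmax):
    """Exhaustive-enumeration oracle for the probability of the observations.

    Walks the generative process forward with scipy.stats pmfs, enumerating
    every latent outcome (P, then each thinning draw) up to ``pmax``
    primaries per year, and accumulates the probability of outcomes matching
    the observed counts.
    """
    n_years = data.n_years

    @lru_cache(maxsize=None)
    def from_year(y: int, s_prev: int) -> float:
        if y == n_years:
            return 1.0
        mu = mean_primaries(s_prev, params.r, params.kappa)
        d1 = float(params.det_active_primary.probability(y))
        d2 = float(params.det_active_secondary.probability(y))
        d3 = float(params.det_inactive_secondary.probability(y))
        total = 0.0
        for P in range(pmax + 1):
            p_P = poisson.pmf(P, mu)
            if data.stage_known[y]:
                for a_p in range(P + 1):
                    p_ap = binom.pmf(a_p, P, d1)
                    for a_s in range(P - a_p + 1):
                        p_as = binom.pmf(a_s, P - a_p, d2)
                        S = P - a_p - a_s
                        for i_s in range(S + 1):
                            if (
                                a_p == data.active_primary[y]
                                and a_s == data.active_secondary[y]
                                and i_s == data.inactive_secondary[y]
                            ):
                                total += (
                                    p_P * p_ap * p_as
                                    * binom.pmf(i_s, S, d3)
                                    * from_year(y + 1, S)
                                )
            else:
                # colony-count year: each colony's secondary is found while
                # active (prob d2) or, failing that, found inactive (prob d3);
                # the detected-colony total counts both outcomes
                S = P - data.removed_unclassified[y]
                if S < 0:
                    continue
                for a in range(P + 1):
                    p_a = binom.pmf(a, P, d2)
                    for i in range(P - a + 1):
                        if a + i == data.colonies[y]:
                            total += (
                                p_P * p_a * binom.pmf(i, P - a, d3)
                                * from_year(y + 1, int(S))
                            )
        return total

    return from_year(0, s_init)


def summed_likelihood(params, s_init, data, pmax):
    """Marginal observation probability from the model's own likelihood."""
    n_years = data.n_years
    total = 0.0
    for latents in np.ndindex(*([pmax + 1] * n_years)):
        ll = log_likelihood(params, LatentState(np.array(latents), s_init), data)
        if np.isfinite(ll):
            total += np.exp(ll)
    return total


class TestLikelihoodAgainstEnumeration:
    def test_two_classified_years(self):
        """Summed likelihood equals the brute-force generative probability."""
        counts = [
            YearlyCounts(2007, 2, 1, 1, 0, 1, 1),
            YearlyCounts(2008, 2, 1, 1, 0, 1, 0),
        ]
        data = CountData.from_yearly_counts(counts)
        params = const_params(3.0, 8.0, 0.4, 0.3, 0.2)
        got = summed_likelihood(params, 2, data, pmax=10)
        want = enumerate_observation_probability(params, 2, data, pmax=10)
        assert got == pytest.approx(want, abs=1e-10)

    def test_unclassified_then_classified_year(self):
        counts = [
            YearlyCounts(2007, 2, 0, 0, 2, 0, 0, 1),
            YearlyCounts(2008, 3, 1, 2, 0, 1, 1),
        ]
        data = CountData.from_yearly_counts(counts)
        params = const_params(2.0, 6.0, 0.35, 0.45, 0.25)
        got = summed_likelihood(params, 1, data, pmax=9)
        want = enumerate_observation_probability(params, 1, data, pmax=9)
        assert got == pytest.approx(want, abs=1e-10)


class TestLogLikelihoodEdges:
    def test_impossible_configuration_is_neg_inf(self):
        counts = [YearlyCounts(2007, 5, 3, 2, 0, 3, 1)]
        data = CountData.from_yearly_counts(counts)
        params = const_params(5.0, 20.0, 0.3, 0.3, 0.3)
        # latent P smaller than the observed removals
        ll = log_likelihood(params, LatentState(np.array([2]), 3), data)
        assert ll == -np.inf

    def test_zero_detection_reduces_to_poisson_term(self):
        counts = [YearlyCounts(2007, 0, 0, 0, 0, 0, 0)]
        data = CountData.from_yearly_counts(counts)
        params = ModelParams(
            r=4.0, kappa=10.0,
            det_active_primary=DetectionSchedule(-40.0),
            det_active_secondary=DetectionSchedule(-40.0),
            det_inactive_secondary=DetectionSchedule(-40.0),
        )
        for P in (0, 3, 7):
            ll = log_likelihood(params, LatentState(np.array([P]), 2), data)
            mu = mean_primaries(2, 4.0, 10.0)
            assert ll == pytest.approx(poisson.logpmf(P, mu), abs=1e-9)


class TestLogPosterior:
    def test_is_likelihood_plus_prior_constant_in_latents(self):
        counts = [
            YearlyCounts(2007, 2, 1, 1, 0, 1, 1),
            YearlyCounts(2008, 2, 1, 1, 0, 1, 0),
        ]
        data = CountData.from_yearly_counts(counts)
        params = const_params(3.0, 8.0, 0.4, 0.3, 0.2)
        priors = PriorSpec()
        diffs = set()
        for P in ([3, 4], [5, 2], [3, 2]):
            lat = LatentState(np.array(P), 2)
            diff = log_posterior(params, lat, data, priors) - log_likelihood(params, lat, data)
            diffs.add(round(diff, 12))
        assert len(diffs) == 1  # prior does not depend on the latent trajectory

    def test_outside_prior_support(self):
        counts = [YearlyCounts(2007, 0, 0, 0, 0, 0, 0)]
        data = CountData.from_yearly_counts(counts)
        params = const_params(3.0, 8.0, 0.4, 0.3, 0.2)
        lat = LatentState(np.array([0]), 999)  # S_init beyond uniform support
        assert log_posterior(params, lat, data) == -np.inf

    def test_matches_recomputation_from_parts(self, rng):
        counts = [
            YearlyCounts(2007, 2, 1, 1, 0, 1, 1),
            YearlyCounts(2008, 2, 1, 1, 0, 1, 0),
        ]
        data = CountData.from_yearly_counts(counts)
        priors = PriorSpec()
        from scipy.stats import norm

        for _ in range(20):
            r = float(np.exp(rng.normal(1.5, 0.5)))
            kappa = float(np.exp(rng.normal(3.0, 0.5)))
            ints = rng.normal(0, 1, size=3)
            slopes = rng.normal(0, 0.2, size=3)
            params = ModelParams(
                r=r, kappa=kappa,
                det_active_primary=DetectionSchedule(*map(float, (ints[0], slopes[0]))),
                det_active_secondary=DetectionSchedule(*map(float, (ints[1], slopes[1]))),
                det_inactive_secondary=DetectionSchedule(*map(float, (ints[2], slopes[2]))),
            )
            lat = LatentState(np.array([4, 5]), 2)
            want = (
                log_likelihood(params, lat, data)
                + norm.logpdf(np.log(r), np.log(5), 1.0)
                + norm.logpdf(np.log(kappa), np.log(50), 1.5)
                + norm.logpdf(ints, 0, 2.0).sum()
                + norm.logpdf(slopes, 0, 0.5).sum()
                - np.log(20)
            )
            assert log_posterior(params, lat, data, priors) == pytest.approx(want, rel=1e-9)


@pytest.fixture(scope="module")
def small_fit():
    """A short fit to a small synthetic dataset (shared across tests)."""
    from velutina.synthetic_data import SyntheticConfig, default_true_params, generate_invasion

    config = SyntheticConfig(true_params=default_true_params(8), seed=5)
    _, counts = generate_invasion(config)
    data = CountData.from_yearly_counts(counts)
    cfg = MCMCConfig(n_iterations=4000, n_burn_in=1000, thinning=5, n_chains=2, seed=3)
    return run_mcmc(data, PriorSpec(), cfg)


class TestRunMcmc:
    def test_identical_seed_identical_chains(self):
        counts = [
            YearlyCounts(2007, 2, 1, 1, 0, 1, 1),
            YearlyCounts(2008, 4, 2, 2, 0, 1, 1),
            YearlyCounts(2009, 6, 2, 4, 0, 2, 2),
        ]
        data = CountData.from_yearly_counts(counts)
        cfg = MCMCConfig(n_iterations=1500, n_burn_in=500, thinning=5, n_chains=2, seed=11)
        a = run_mcmc(data, None, cfg)
        b = run_mcmc(data, None, cfg)
        for k in a.samples:
            assert np.array_equal(a.samples[k], b.samples[k])

    def test_chain_is_well_formed(self, small_fit):
        chain = small_fit
        assert np.isfinite(chain.flat("log_posterior")).all()
        assert chain.n_chains == 2
        # latent trajectories always dominate their observed counts
        assert (chain.flat("P") >= 0).all()
        for rate in chain.acceptance.values():
            assert 0.0 <= rate <= 1.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iterations=100, n_burn_in=100)


class TestSummaries:
    def test_constant_chain_zero_width(self):
        df = summarize_samples({"x": np.full(500, 3.25)})
        row = df.loc["x"]
        assert row["median"] == row["mean"] == 3.25
        assert row["ci_low"] == row["ci_high"] == 3.25

    def test_normal_quantiles(self, rng):
        x = rng.standard_normal(1_000_000)
        lo, hi = credible_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.01)
        assert hi == pytest.approx(1.96, abs=0.01)

    def test_summary_includes_derived_quantities(self, small_fit):
        df = summarize_posterior(small_fit)
        for q in ("r", "kappa", "K_no_control", "K_control",
                  "E_discoveries_active_primary", "pct_discovered_ever"):
            assert q in df.index
            assert df.loc[q, "ci_low"] <= df.loc[q, "median"] <= df.loc[q, "ci_high"]

    def test_empty_chain_rejected(self, small_fit):
        import dataclasses

        empty = dataclasses.replace(
            small_fit, samples={k: v[:, :0] for k, v in small_fit.samples.items()}
        )
        with pytest.raises(ValueError):
            summarize_posterior(empty)

    def test_diagnostics_report_rhat_and_ess(self, small_fit):
        df = diagnostics(small_fit)
        assert {"rhat", "ess"} <= set(df.columns)
        assert (df["ess"] > 0).all()


class TestDiscoveryPercentages:
    def test_active_never_exceeds_ever_per_sample(self, small_fit):
        d = small_fit.derived()
        assert (d["pct_discovered_active"] <= d["pct_discovered_ever"] + 1e-12).all()

    def test_detection_limits(self):
        # with no detection nothing is ever discovered; with certain
        # detection of active nests every colony is discovered
        base = dict(r=9.0, kappa=25.0)
        lo = const_params(**base, d_ap=1e-15, d_as=1e-15, d_is=1e-15)
        hi = const_params(**base, d_ap=1 - 1e-15, d_as=0.5, d_is=0.5)
        for params, expected in ((lo, 0.0), (hi, 100.0)):
            d1 = params.det_active_primary.probability(0)
            d2 = params.det_active_secondary.probability(0)
            d3 = params.det_inactive_secondary.probability(0)
            q = (1 - d1) * (1 - d2)
            pct = 100 * (d1 + (1 - d1) * d2 + q * d3)
            assert pct == pytest.approx(expected, abs=1e-9)

    def test_summary_table(self, small_fit):
        df = discovery_percentages(small_fit)
        assert "pct_discovered_ever" in df.index
        assert (df["median"] >= 0).all() and (df["median"] <= 100).all()
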