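"""Rectangle probabilities, their invariants, and posterior LDBM summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ndtr
from scipy.stats import multivariate_normal

import latentdbm as ldbm
from latentdbm.prevalence import bvn_cdf


def mc_rectangle(params, n_draws, seed, t1=-2.0, t2=2.0):
    """Monte-Carlo oracle: fraction of simulated children in the DBM quadrant."""
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_draws)
    z2 = params.rho * z1 + np.sqrt(1 - params.rho**2) * rng.standard_normal(n_draws)
    y1 = params.mu[0] + params.sigma[0] * z1
    y2 = params.mu[1] + params.sigma[1] * z2
    hits = (y1 < t1) & (y2 > t2)
    p = hits.mean()
    se = np.sqrt(max(p * (1 - p), 1e-12) / n_draws)
    return p, se


class TestBvnCdf:
    def test_matches_scipy(self, rng):
        for _ in range(50):
            h, k = rng.normal(scale=2, size=2)
            r = rng.uniform(-0.99, 0.99)
            ref = multivariate_normal(mean=[0, 0], cov=[[1, r], [r, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, r) == pytest.approx(ref, abs=1e-9)

    def test_axis_cases(self):
        assert bvn_cdf(0, 0, 0.5) == pytest.approx(0.25 + np.arcsin(0.5) / (2 * np.pi),
                                                   abs=1e-14)
        ref = multivariate_normal(mean=[0, 0], cov=[[1, 0.3], [0.3, 1]]).cdf([0, -1.2])
        assert bvn_cdf(0, -1.2, 0.3) == pytest.approx(ref, abs=1e-9)

    def test_degenerate_correlations(self):
        assert bvn_cdf(0.5, 1.5, 1.0) == pytest.approx(ndtr(0.5), abs=1e-14)
        assert bvn_cdf(-0.5, 0.2, -1.0) == pytest.approx(
            max(0.0, ndtr(-0.5) + ndtr(0.2) - 1), abs=1e-14
        )

    def test_vectorized(self):
        h = np.array([0.0, 1.0, -1.0])
        out = bvn_cdf(h, 0.5, 0.2)
        assert out.shape == (3,)


class TestRectangleProbability:
    def test_independence_closed_form(self):
        p = ldbm.rectangle_probability(ldbm.ModelParams(mu=(0, 0), sigma=(1, 1), rho=0.0))
        assert p == pytest.approx(ndtr(-2.0) ** 2, abs=1e-10)

    def test_antithetic_limit(self):
        p = ldbm.rectangle_probability(ldbm.ModelParams(mu=(0, 0), sigma=(1, 1), rho=-1.0))
        assert p == pytest.approx(ndtr(-2.0), abs=1e-10)

    def test_comonotone_limit(self):
        p = ldbm.rectangle_probability(ldbm.ModelParams(mu=(0, 0), sigma=(1, 1), rho=1.0))
        assert p == 0.0

    def test_against_mc_oracle(self):
        params = ldbm.ModelParams(mu=(-1.0, 1.0), sigma=(1.2, 0.8), rho=-0.4)
        p_mc, se = mc_rectangle(params, 2_000_000, seed=42)
        assert ldbm.rectangle_probability(params) == pytest.approx(p_mc, abs=4 * se)

    def test_strictly_decreasing_in_rho(self):
        params = [ldbm.ModelParams(mu=(-1, 1), sigma=(1.2, 0.8), rho=r)
                  for r in np.linspace(-0.95, 0.95, 21)]
        vals = [ldbm.rectangle_probability(p) for p in params]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_event_monotonicity_in_thresholds(self):
        p = ldbm.ModelParams(mu=(-1, 1), sigma=(1, 1), rho=0.1)
        base = ldbm.rectangle_probability(p, ldbm.Thresholds())
        wider_t1 = ldbm.rectangle_probability(p, ldbm.Thresholds(t1=-1.5))
        tighter_t2 = ldbm.rectangle_probability(p, ldbm.Thresholds(t2=2.5))
        assert wider_t1 >= base >= tighter_t2

    @given(
        mu1=st.floats(-2, 2), mu2=st.floats(-2, 2),
        s1=st.floats(0.3, 2.5), s2=st.floats(0.3, 2.5),
        rho=st.floats(-0.99, 0.99),
    )
    def test_frechet_bound(self, mu1, mu2, s1, s2, rho):
        p = ldbm.ModelParams(mu=(mu1, mu2), sigma=(s1, s2), rho=rho)
        u1 = (-2 - mu1) / s1
        u2 = (2 - mu2) / s2
        val = ldbm.rectangle_probability(p)
        assert 0.0 <= val <= min(ndtr(u1), 1 - ndtr(u2)) + 1e-12

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            ldbm.ModelParams(mu=(0, 0), sigma=(0.0, 1), rho=0.0)


class TestPosteriorLdbm:
    def test_degenerate_posterior(self):
        params = ldbm.ModelParams(mu=(-1, 1), sigma=(1, 1), rho=-0.3)
        draws = _constant_draws(params, 100)
        p = ldbm.posterior_ldbm(draws)
        assert np.allclose(p, ldbm.rectangle_probability(params))

    def test_marginalization_applied(self):
        params = ldbm.ModelParams(mu=(-1, 1), sigma=(1, 1), rho=0.5)
        eff = ldbm.HouseholdEffect(tau=(1.0, 0.0), active=(True, False))
        draws = _constant_draws(params, 10, tau=(1.0, 0.0), effect=eff)
        p = ldbm.posterior_ldbm(draws)
        expected = ldbm.rectangle_probability(ldbm.marginal_params(params, eff))
        assert np.allclose(p, expected)

    def test_agrees_with_per_draw_simulation(self, fitted_sample):
        """Posterior-mean LDBM ~ fraction of children simulated from each draw
        who land in the DBM quadrant (spot check on a thinned subset)."""
        _, draws = fitted_sample
        rng = np.random.default_rng(0)
        idx = rng.choice(draws.n_draws, size=200, replace=False)
        sims = []
        for m in idx:
            params, _ = draws.params_at(m)
            p_mc, _ = mc_rectangle(params, 4000, seed=int(rng.integers(2**31)))
            sims.append(p_mc)
        analytic = ldbm.posterior_ldbm(draws)[idx]
        diff = np.mean(sims) - np.mean(analytic)
        se = np.std(np.array(sims) - analytic) / np.sqrt(len(idx))
        assert abs(diff) < 4 * max(se, 1e-4)


class TestSummaries:
    def test_exceedance_counting(self):
        draws = np.array([0.005, 0.02, 0.04])
        assert ldbm.exceedance(draws, 0.01) == pytest.approx(2 / 3)
        assert ldbm.exceedance(draws, 0.0) == 1.0
        assert ldbm.exceedance(draws, 1.0) == 0.0

    def test_exceedance_monotone_in_cutoff(self, rng):
        draws = rng.uniform(size=500)
        cuts = np.linspace(0.01, 0.99, 20)
        vals = [ldbm.exceedance(draws, c) for c in cuts]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_exceedance_empty_rejected(self):
        with pytest.raises(ValueError):
            ldbm.exceedance(np.array([]), 0.01)

    def test_credible_interval_quantiles(self):
        grid = np.linspace(0, 1, 101)
        lo, hi = ldbm.credible_interval(grid, 0.95)
        assert lo == pytest.approx(0.025, abs=1e-9)
        assert hi == pytest.approx(0.975, abs=1e-9)
        c = np.full(10, 0.3)
        assert ldbm.credible_interval(c, 0.95) == (pytest.approx(0.3), pytest.approx(0.3))

    @given(level_small=st.floats(0.2, 0.5), level_big=st.floats(0.6, 0.99))
    def test_nested_levels(self, level_small, level_big):
        rng = np.random.default_rng(12)
        draws = rng.beta(2, 30, size=400)
        lo_s, hi_s = ldbm.credible_interval(draws, level_small)
        lo_b, hi_b = ldbm.credible_interval(draws, level_big)
        assert lo_b <= lo_s <= hi_s <= hi_b

    def test_prob_rho_positive(self):
        params = ldbm.ModelParams(mu=(0, 0), sigma=(1, 1), rho=-0.5)
        draws = _constant_draws(params, 10)
        assert ldbm.prob_rho_positive(draws) == 0.0
        sym = _constant_draws(params, 10)
        sym.rho = np.array([-0.2, 0.2] * 5)
        assert ldbm.prob_rho_positive(sym) == pytest.approx(0.5)

    def test_rho_recovery(self):
        """Strong positive correlation at n = 300 yields Pr(rho > 0) > 0.95."""
        truth = ldbm.SubpopTruth(mu=(0, 0), sigma=(1, 1), rho=0.6, n_households=300)
        df = ldbm.generate_subpopulation(truth, "r", "rural", seed=6)
        s = ldbm.group_by_subpopulation(df)[0]
        cfg = ldbm.MCMCConfig(n_chains=2, warmup=500, stored_samples_total=2000,
                              thin=2, seed=1)
        d = ldbm.fit_posterior(s, config=cfg)
        assert ldbm.prob_rho_positive(d) > 0.95

    def test_summary_object(self, fitted_sample):
        _, draws = fitted_sample
        s = ldbm.summarize_ldbm(draws)
        assert 0 <= s.ci_low <= s.median <= s.ci_high <= 1
        assert s.exceedance[0.01] >= s.exceedance[0.03]


def _constant_draws(params, m, tau=None, effect=None):
    return ldbm.PosteriorSamples(
        mu=np.tile(params.mu, (m, 1)),
        sigma=np.tile(params.sigma, (m, 1)),
        rho=np.full(m, params.rho),
        tau=None if tau is None else np.tile(tau, (m, 1)),
        chain=np.zeros(m, dtype=int),
        effect=effect or ldbm.HouseholdEffect.none(),
        config=ldbm.MCMCConfig(n_chains=2, stored_samples_total=m if m % 2 == 0 else m * 2),
    )
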