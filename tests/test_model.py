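"""Likelihood exactness, priors, ML fits and posterior sampling contracts."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

import latentdbm as ldbm
from latentdbm.model import BivariateNormalModel, marginal_params


def dense_block_loglik(y, households, params, tau):
    """Brute-force oracle: one joint Gaussian over all children, with
    Sigma + Sigma_w blocks on within-household cross terms."""
    n = len(y)
    Sigma = params.cov
    Sw = np.diag(np.square(tau))
    big = np.zeros((2 * n, 2 * n))
    for i in range(n):
        for j in range(n):
            blk = np.zeros((2, 2))
            if i == j:
                blk += Sigma
            if households[i] == households[j]:
                blk += Sw
            big[2 * i:2 * i + 2, 2 * j:2 * j + 2] = blk
    mean = np.tile(params.mu, n)
    return multivariate_normal(mean=mean, cov=big).logpdf(np.asarray(y).ravel())


class TestLogLikelihood:
    def test_standard_normal_at_origin(self):
        m = BivariateNormalModel([[0.0, 0.0]])
        p = ldbm.ModelParams(mu=(0, 0), sigma=(1, 1), rho=0.0)
        assert m.loglike(p) == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_independence_factorization(self, rng):
        y = rng.normal(size=(25, 2))
        p = ldbm.ModelParams(mu=(0.3, -0.1), sigma=(1.4, 0.7), rho=0.0)
        m = BivariateNormalModel(y)
        expected = (norm(0.3, 1.4).logpdf(y[:, 0]).sum()
                    + norm(-0.1, 0.7).logpdf(y[:, 1]).sum())
        assert m.loglike(p) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_clustered_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 20))
        households = rng.integers(0, max(2, n // 2), size=n)
        y = rng.normal(size=(n, 2))
        params = ldbm.ModelParams(
            mu=tuple(rng.normal(size=2)),
            sigma=tuple(np.exp(rng.normal(scale=0.3, size=2))),
            rho=float(rng.uniform(-0.8, 0.8)),
        )
        tau = tuple(np.abs(rng.normal(scale=0.7, size=2)))
        eff = ldbm.HouseholdEffect(tau=tau, active=(True, True))
        m = BivariateNormalModel(y, groups=households, effect=eff)
        assert m.loglike(params, tau=tau) == pytest.approx(
            dense_block_loglik(y, households, params, tau), abs=1e-8
        )

    def test_zero_tau_equals_iid(self, rng):
        y = rng.normal(size=(12, 2))
        hh = rng.integers(0, 4, size=12)
        p = ldbm.ModelParams(mu=(0, 0), sigma=(1.2, 0.9), rho=0.4)
        eff = ldbm.HouseholdEffect(tau=(0, 0), active=(True, True))
        clustered = BivariateNormalModel(y, groups=hh, effect=eff).loglike(p, tau=(0, 0))
        iid = BivariateNormalModel(y).loglike(p)
        assert clustered == pytest.approx(iid, abs=1e-10)

    def test_singular_rho_rejected(self):
        m = BivariateNormalModel([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="rho"):
            m.loglike(ldbm.ModelParams(mu=(0, 0), sigma=(1, 1), rho=1.0))


class TestLogPrior:
    def test_sd_terms(self):
        base = ldbm.log_prior(ldbm.ModelParams(mu=(0, 0), sigma=(1, 1), rho=0.0))
        assert base == pytest.approx(0.0)
        e = ldbm.log_prior(ldbm.ModelParams(mu=(5, -5), sigma=(np.e, 1), rho=0.0))
        assert e == pytest.approx(-1.0)

    def test_uniform_in_rho(self):
        a = ldbm.log_prior(ldbm.ModelParams(mu=(0, 0), sigma=(1, 1), rho=0.5))
        b = ldbm.log_prior(ldbm.ModelParams(mu=(0, 0), sigma=(1, 1), rho=-0.5))
        assert a == b

    def test_out_of_support(self):
        assert ldbm.log_prior(ldbm.ModelParams(mu=(0, 0), sigma=(1, 1), rho=1.0)) == -np.inf


class TestMarginalParams:
    def test_identity_when_tau_zero(self):
        p = ldbm.ModelParams(mu=(-1, 1), sigma=(1.2, 0.8), rho=-0.4)
        assert marginal_params(p, ldbm.HouseholdEffect.none()) is p

    def test_closed_form(self):
        p = ldbm.ModelParams(mu=(0, 0), sigma=(1, 1), rho=0.5)
        eff = ldbm.HouseholdEffect(tau=(1.0, 0.0), active=(True, False))
        m = marginal_params(p, eff)
        assert m.sigma[0] == pytest.approx(np.sqrt(2))
        assert m.sigma[1] == pytest.approx(1.0)
        assert m.rho == pytest.approx(0.5 / np.sqrt(2))

    def test_simulation_oracle(self, rng):
        """Empirical covariance of clustered draws matches diag(tau^2) + Sigma."""
        truth = ldbm.SubpopTruth(mu=(0.2, -0.4), sigma=(1.1, 0.8), rho=0.35,
                                 tau=(0.6, 0.9), n_households=1)
        y = np.concatenate(
            [ldbm.generate_household(truth, 2, rng) for _ in range(25_000)]
        )
        emp = np.cov(y.T)
        target = truth.marginal_cov
        n = len(y)
        for i in range(2):
            for j in range(2):
                se = np.sqrt((target[i, i] * target[j, j] + target[i, j] ** 2) / n)
                assert abs(emp[i, j] - target[i, j]) < 4 * se


class TestMaximumLikelihood:
    def test_closed_form_self_consistency(self, rng):
        y = rng.normal(size=(40, 2)) @ np.array([[1.0, 0.3], [0.0, 0.8]])
        s = _as_sample(y)
        res = ldbm.fit_ml(s)
        assert res.loglik == pytest.approx(
            ldbm.log_likelihood(res.params, ldbm.HouseholdEffect.none(), s), abs=1e-10
        )
        assert res.params.mu == pytest.approx(tuple(y.mean(axis=0)))
        cov = np.cov(y.T, ddof=0)
        assert res.params.sigma[0] == pytest.approx(np.sqrt(cov[0, 0]))
        assert res.aic == pytest.approx(10 - 2 * res.loglik)

    def test_boundary_recovery_on_null_data(self):
        """Clustered fit on independent data returns tau on/near the boundary."""
        truth = ldbm.SubpopTruth(mu=(0, 0), sigma=(1, 1), rho=0.3, n_households=60,
                                 children_per_household={1: 0.3, 2: 0.6, 3: 0.1})
        best = None
        for seed in range(4):
            df = ldbm.generate_subpopulation(truth, "C", "rural", seed=seed)
            s = ldbm.group_by_subpopulation(df)[0]
            r0 = ldbm.fit_ml(s)
            r1 = ldbm.fit_ml(s, effect=ldbm.HouseholdEffect(tau=(0, 0), active=(True, True)))
            assert r1.loglik >= r0.loglik - 1e-8   # nesting
            if best is None or r1.loglik - r0.loglik < best[0]:
                best = (r1.loglik - r0.loglik, r1)
        # at least one null replicate lands on the boundary
        dll, r1 = best
        assert dll < 1e-4
        assert max(r1.effect.tau) < 0.05

    def test_aic_difference_identity(self, rng):
        y = rng.normal(size=(30, 2))
        hh = np.repeat(np.arange(15), 2)
        s = _as_sample(y, hh)
        r0 = ldbm.fit_ml(s)
        r1 = ldbm.fit_ml(s, effect=ldbm.HouseholdEffect(tau=(0, 0), active=(True, False)))
        assert (r1.aic - r0.aic) == pytest.approx(
            2 * (r1.n_params - r0.n_params) - 2 * (r1.loglik - r0.loglik), abs=1e-10
        )

    def test_summary_table(self, rng):
        y = rng.normal(size=(60, 2))
        res = ldbm.fit_ml(_as_sample(y))
        tab = res.summary()
        assert list(tab.index) == ["mu_haz", "mu_baz", "sigma_haz", "sigma_baz", "rho"]
        # mu standard error approx sigma/sqrt(n)
        assert tab.loc["mu_haz", "std_err"] == pytest.approx(
            res.params.sigma[0] / np.sqrt(60), rel=0.05
        )


class TestPosterior:
    def test_determinism(self, quick_mcmc, rural_jutai_truth):
        df = ldbm.generate_subpopulation(rural_jutai_truth, "J", "rural", seed=2)
        s = ldbm.group_by_subpopulation(df)[0]
        d1 = ldbm.fit_posterior(s, config=quick_mcmc)
        d2 = ldbm.fit_posterior(s, config=quick_mcmc)
        assert np.array_equal(d1.rho, d2.rho)
        assert np.array_equal(d1.mu, d2.mu)

    def test_supports_and_size(self, fitted_sample):
        _, draws = fitted_sample
        assert draws.n_draws == draws.config.stored_samples_total
        assert np.all(draws.sigma > 0)
        assert np.all(np.abs(draws.rho) < 1)

    def test_recovery_within_three_posterior_sd(self, fitted_sample, rural_jutai_truth):
        _, draws = fitted_sample
        truth = [rural_jutai_truth.mu[0], rural_jutai_truth.mu[1],
                 rural_jutai_truth.sigma[0], rural_jutai_truth.sigma[1],
                 rural_jutai_truth.rho]
        arrays = [draws.mu[:, 0], draws.mu[:, 1], draws.sigma[:, 0], draws.sigma[:, 1],
                  draws.rho]
        for a, t in zip(arrays, truth):
            assert abs(np.mean(a) - t) < 3 * np.std(a)

    def test_large_n_agrees_with_mle(self):
        """Flat priors: posterior mean of mu within 0.02 z of the sample mean."""
        truth = ldbm.SubpopTruth(mu=(-1.0, 1.0), sigma=(1, 1), rho=-0.4, n_households=2000)
        df = ldbm.generate_subpopulation(truth, "big", "urban", seed=4)
        s = ldbm.group_by_subpopulation(df)[0]
        cfg = ldbm.MCMCConfig(n_chains=2, warmup=600, stored_samples_total=4000,
                              thin=3, seed=8)
        d = ldbm.fit_posterior(s, config=cfg)
        ybar = s.y.mean(axis=0)
        assert abs(d.mu[:, 0].mean() - ybar[0]) < 0.02
        assert abs(d.mu[:, 1].mean() - ybar[1]) < 0.02

    def test_posterior_sd_shrinks_with_n(self):
        sds = []
        for n, seed in [(50, 0), (500, 1), (5000, 2)]:
            truth = ldbm.SubpopTruth(mu=(0, 0), sigma=(1, 1), rho=0.2, n_households=n)
            df = ldbm.generate_subpopulation(truth, "x", "rural", seed=seed)
            s = ldbm.group_by_subpopulation(df)[0]
            cfg = ldbm.MCMCConfig(n_chains=2, warmup=500, stored_samples_total=2000,
                                  thin=2, seed=seed)
            d = ldbm.fit_posterior(s, config=cfg)
            sds.append(d.mu[:, 0].std())
        assert sds[0] > sds[1] > sds[2]

    def test_refuses_tiny_samples(self):
        s = _as_sample(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="n=2"):
            ldbm.fit_posterior(s)

    def test_warns_below_ten(self, quick_mcmc, rng):
        s = _as_sample(rng.normal(size=(6, 2)))
        with pytest.warns(UserWarning, match="n=6"):
            ldbm.fit_posterior(s, config=quick_mcmc)

    def test_save_artifacts(self, fitted_sample, tmp_path):
        _, draws = fitted_sample
        csv = tmp_path / "posterior.csv"
        draws.save(csv)
        assert csv.exists() and (tmp_path / "posterior.meta.json").exists()
        import pandas as pd
        back = pd.read_csv(csv)
        assert {"chain", "mu_haz", "rho"} <= set(back.columns)
        assert len(back) == draws.n_draws


def _as_sample(y, households=None):
    import pandas as pd

    n = len(y)
    hh = households if households is not None else np.arange(n)
    df = pd.DataFrame(
        {
            "child_id": [f"c{i}" for i in range(n)],
            "household_id": [f"h{h}" for h in hh],
            "municipality": "M",
            "area": "rural",
            "age_months": 24,
            "haz": np.asarray(y)[:, 0],
            "baz": np.asarray(y)[:, 1],
        }
    )
    return ldbm.group_by_subpopulation(df)[0]
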