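"""Bayesian and maximum-likelihood fitting of the bivariate anthropometry model.

Within one subpopulation the (HAZ, BAZ) pair of child ``k`` is modelled
as bivariate normal,

    Y_k ~ MVN(mu, Sigma),    Sigma = [[s1^2, rho*s1*s2], [rho*s1*s2, s2^2]],

optionally extended with a household-level random effect: children of
household ``h`` share an additive deviation ``W_h ~ MVN(0, Sigma_w)``
with diagonal ``Sigma_w = diag(tau1^2, tau2^2)``, so that conditionally
``Y_hk | W_h ~ MVN(mu + W_h, Sigma)`` and marginally
``Y_hk ~ MVN(mu, Sigma_w + Sigma)`` with equicorrelated household blocks.
The clustered marginal likelihood is evaluated analytically (no Monte
Carlo): within-household contrasts depend only on Sigma while household
means of size ``s`` are MVN(mu, Sigma_w + Sigma/s), which reduces the
whole likelihood to a handful of sufficient statistics.

Priors follow the weakly-informative reference choice: flat on both
means, log-flat on both standard deviations (pi(sigma) ~ 1/sigma),
uniform on the correlation over (-1, 1), and (when a random effect is
active) flat on the household-effect SD tau >= 0.  Sampling runs on the
unconstrained scale (log sigma, atanh rho, log tau) with the exact
Jacobian so these priors hold on the natural scale.  The sampler is the
affine-invariant ensemble sampler (emcee), well suited to this smooth
5-7 dimensional posterior; convergence is checked with split-R-hat and
effective sample sizes via arviz.

The public surface follows the Model/Results idiom: build a
:class:`BivariateNormalModel` from data, call :meth:`~BivariateNormalModel.fit`
for maximum likelihood (used by model selection) or
:meth:`~BivariateNormalModel.fit_bayes` for the posterior, and read
estimates, uncertainties and diagnostics off the returned results object.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import emcee
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import SubpopulationSample

__all__ = [
    "ModelParams",
    "HouseholdEffect",
    "MCMCConfig",
    "PosteriorSamples",
    "BivariateMLResults",
    "BivariateNormalModel",
    "ConvergenceWarning",
    "log_likelihood",
    "log_prior",
    "fit_posterior",
    "fit_ml",
    "marginal_params",
]

_LOG_2PI = np.log(2.0 * np.pi)


class ConvergenceWarning(UserWarning):
    """MCMC or optimizer convergence could not be certified."""


@dataclass(frozen=True)
class ModelParams:
    """Mean vector, marginal SDs and correlation of one subpopulation."""

    mu: tuple[float, float]
    sigma: tuple[float, float]
    rho: float

    def __post_init__(self):
        if not (self.sigma[0] > 0 and self.sigma[1] > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")

    @property
    def cov(self) -> np.ndarray:
        s1, s2 = self.sigma
        off = self.rho * s1 * s2
        return np.array([[s1 * s1, off], [off, s2 * s2]])


@dataclass(frozen=True)
class HouseholdEffect:
    """Household random-effect specification: SDs tau and active flags.

    ``active = (False, False)`` is the model without random effects; a
    single active outcome corresponds to a unidimensional W_h.  The tau
    component is pinned at 0 wherever the flag is inactive.
    """

    tau: tuple[float, float] = (0.0, 0.0)
    active: tuple[bool, bool] = (False, False)

    def __post_init__(self):
        for l in range(2):
            if self.tau[l] < 0:
                raise ValueError("tau must be non-negative")
            if not self.active[l] and self.tau[l] != 0.0:
                raise ValueError("tau must be 0 for inactive outcomes")

    @property
    def any_active(self) -> bool:
        return self.active[0] or self.active[1]

    @property
    def n_active(self) -> int:
        return int(self.active[0]) + int(self.active[1])

    @classmethod
    def none(cls) -> "HouseholdEffect":
        return cls()


@dataclass(frozen=True)
class MCMCConfig:
    """Posterior sampling configuration.

    ``stored_samples_total`` (M) is the total number of stored draws
    pooled across ``n_chains`` independent ensemble runs; the default
    M = 20,000 is the analysis standard for stable 3-decimal exceedance
    probabilities.  ``warmup`` is per-chain adaptation steps (discarded);
    ``thin`` controls post-warmup thinning of ensemble steps.
    ``target_accept`` is kept for samplers with step-size adaptation and
    is inert for the ensemble sampler.
    """

    n_chains: int = 4
    warmup: int = 1000
    stored_samples_total: int = 20_000
    seed: int = 0
    target_accept: float = 0.9
    n_walkers: int = 16
    thin: int = 3

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for split-R-hat")
        if self.stored_samples_total % self.n_chains:
            raise ValueError("stored_samples_total must be divisible by n_chains")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")


# ---------------------------------------------------------------------------
# sufficient statistics


@dataclass(frozen=True)
class _SuffStats:
    """Sufficient statistics of one subpopulation for the Gaussian likelihoods.

    ``n``/``ybar``/``scatter`` suffice for the iid model.  For clustered
    likelihoods: ``n_households``, the total within-household scatter
    ``within_scatter``, and per distinct household size ``s`` the count,
    mean and centered scatter of the household means.
    """

    n: int
    ybar: np.ndarray
    scatter: np.ndarray
    n_households: int
    within_scatter: np.ndarray
    sizes: np.ndarray            # distinct household sizes
    size_counts: np.ndarray      # households per size
    size_means: np.ndarray       # (len(sizes), 2) mean of household means
    size_scatters: np.ndarray    # (len(sizes), 2, 2) centered scatter of household means
    log_size_jacobian: float     # -(d/2) * sum_h log s_h for the mean/contrast transform

    @classmethod
    def from_arrays(cls, y: np.ndarray, households: np.ndarray) -> "_SuffStats":
        y = np.asarray(y, dtype=float)
        n = len(y)
        ybar = y.mean(axis=0)
        d = y - ybar
        scatter = d.T @ d

        codes = np.unique(households, return_inverse=True)[1]
        H = codes.max() + 1
        counts = np.bincount(codes, minlength=H).astype(float)
        hmeans = np.stack(
            [np.bincount(codes, weights=y[:, l], minlength=H) / counts for l in range(2)],
            axis=1,
        )
        resid = y - hmeans[codes]
        within = resid.T @ resid

        sizes = np.unique(counts).astype(int)
        size_counts, size_means, size_scatters = [], [], []
        for s in sizes:
            b = hmeans[counts == s]
            m = len(b)
            bbar = b.mean(axis=0)
            db = b - bbar
            size_counts.append(m)
            size_means.append(bbar)
            size_scatters.append(db.T @ db)
        return cls(
            n=n,
            ybar=ybar,
            scatter=scatter,
            n_households=int(H),
            within_scatter=within,
            sizes=sizes,
            size_counts=np.array(size_counts, dtype=float),
            size_means=np.array(size_means, dtype=float),
            size_scatters=np.array(size_scatters, dtype=float),
            log_size_jacobian=float(-np.sum(np.log(counts))),
        )


def _gauss_suff_ll(m, xbar, S, mu1, mu2, c11, c12, c22):
    """Sum of m bivariate-normal log-densities with common covariance C.

    All covariance arguments may be walker-shaped arrays; (m, xbar, S) are
    the data-side count, mean and centered scatter of the group.
    """
    det = c11 * c22 - c12 * c12
    i11 = c22 / det
    i22 = c11 / det
    i12 = -c12 / det
    tr = i11 * S[0, 0] + 2.0 * i12 * S[0, 1] + i22 * S[1, 1]
    d1 = xbar[0] - mu1
    d2 = xbar[1] - mu2
    quad = i11 * d1 * d1 + 2.0 * i12 * d1 * d2 + i22 * d2 * d2
    return -m * _LOG_2PI - 0.5 * m * np.log(det) - 0.5 * (tr + m * quad)


def _loglike_batch(stats: _SuffStats, active: tuple[bool, bool],
                   mu1, mu2, s1, s2, rho, tau1, tau2):
    """Marginal log-likelihood, vectorized over walker-shaped parameter arrays."""
    v1 = s1 * s1
    v2 = s2 * s2
    cov = rho * s1 * s2
    if not (active[0] or active[1]):
        return _gauss_suff_ll(stats.n, stats.ybar, stats.scatter, mu1, mu2, v1, cov, v2)

    # within-household contrasts: (n - H) bivariate normals with covariance Sigma
    n_con = stats.n - stats.n_households
    det = v1 * v2 - cov * cov
    i11 = v2 / det
    i22 = v1 / det
    i12 = -cov / det
    SW = stats.within_scatter
    tr = i11 * SW[0, 0] + 2.0 * i12 * SW[0, 1] + i22 * SW[1, 1]
    # log_size_jacobian accounts for using household means (not orthonormal
    # mean components) in the between-household factor below
    ll = -n_con * _LOG_2PI - 0.5 * n_con * np.log(det) - 0.5 * tr + stats.log_size_jacobian

    # household means of size s: MVN(mu, Sigma_w + Sigma/s)
    t1sq = tau1 * tau1
    t2sq = tau2 * tau2
    for idx, s in enumerate(stats.sizes):
        ll = ll + _gauss_suff_ll(
            stats.size_counts[idx], stats.size_means[idx], stats.size_scatters[idx],
            mu1, mu2, t1sq + v1 / s, cov / s, t2sq + v2 / s,
        )
    return ll


# ---------------------------------------------------------------------------
# results objects


@dataclass
class BivariateMLResults:
    """Maximum-likelihood fit of one subpopulation.

    ``params`` holds the conditional (within-household) parameters;
    ``effect`` carries the fitted tau.  ``bse`` are asymptotic standard
    errors from the numerically inverted observed information, in the
    order (mu1, mu2, sigma1, sigma2, rho, tau_active...), or None when
    the information matrix is not invertible (e.g. tau on the boundary).
    """

    model: "BivariateNormalModel"
    params: ModelParams
    effect: HouseholdEffect
    loglik: float
    n_params: int
    converged: bool = True
    bse: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def marginal(self) -> ModelParams:
        return marginal_params(self.params, self.effect)

    def summary(self) -> pd.DataFrame:
        names = ["mu_haz", "mu_baz", "sigma_haz", "sigma_baz", "rho"]
        est = [*self.params.mu, *self.params.sigma, self.params.rho]
        for l, name in ((0, "tau_haz"), (1, "tau_baz")):
            if self.effect.active[l]:
                names.append(name)
                est.append(self.effect.tau[l])
        bse = self.bse if self.bse is not None else [np.nan] * len(est)
        return pd.DataFrame({"estimate": est, "std_err": list(bse)[: len(est)]}, index=names)


@dataclass
class PosteriorSamples:
    """Stored posterior draws for one subpopulation and their diagnostics.

    Arrays are pooled across chains in chain order (M rows total);
    ``chain`` maps each draw to its chain.  ``rhat``/``ess`` are computed
    on the natural-scale parameters from the walker-level chains before
    thinning, so they reflect the sampler's true autocorrelation.
    """

    mu: np.ndarray            # (M, 2)
    sigma: np.ndarray         # (M, 2)
    rho: np.ndarray           # (M,)
    tau: np.ndarray | None    # (M, 2) or None
    chain: np.ndarray         # (M,) chain index per draw
    effect: HouseholdEffect
    config: MCMCConfig
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    key: tuple[str, str] | None = None

    def __post_init__(self):
        if np.any(self.sigma <= 0) or np.any(np.abs(self.rho) >= 1):
            raise ValueError("posterior draws outside the parameter support")

    @property
    def n_draws(self) -> int:
        return len(self.rho)

    def to_frame(self) -> pd.DataFrame:
        out = {
            "chain": self.chain,
            "mu_haz": self.mu[:, 0],
            "mu_baz": self.mu[:, 1],
            "sigma_haz": self.sigma[:, 0],
            "sigma_baz": self.sigma[:, 1],
            "rho": self.rho,
        }
        if self.tau is not None:
            if self.effect.active[0]:
                out["tau_haz"] = self.tau[:, 0]
            if self.effect.active[1]:
                out["tau_baz"] = self.tau[:, 1]
        return pd.DataFrame(out)

    def params_at(self, m: int) -> tuple[ModelParams, HouseholdEffect]:
        p = ModelParams(
            mu=(float(self.mu[m, 0]), float(self.mu[m, 1])),
            sigma=(float(self.sigma[m, 0]), float(self.sigma[m, 1])),
            rho=float(self.rho[m]),
        )
        eff = self.effect
        if self.tau is not None:
            eff = replace(eff, tau=(float(self.tau[m, 0]), float(self.tau[m, 1])))
        return p, eff

    def summary(self, ci_level: float = 0.95) -> pd.DataFrame:
        df = self.to_frame().drop(columns="chain")
        a = (1 - ci_level) / 2
        tab = pd.DataFrame(
            {
                "mean": df.mean(),
                "sd": df.std(ddof=1),
                "median": df.median(),
                f"ci_{100 * a:g}%": df.quantile(a),
                f"ci_{100 * (1 - a):g}%": df.quantile(1 - a),
                "rhat": pd.Series(self.rhat),
                "ess": pd.Series(self.ess),
            }
        )
        return tab

    def save(self, csv_path, meta_path=None) -> None:
        """Persist draws to CSV with a JSON sidecar of diagnostics and config."""
        self.to_frame().to_csv(csv_path, index=False, float_format="%.10g")
        if meta_path is None:
            meta_path = str(csv_path).rsplit(".", 1)[0] + ".meta.json"
        meta = {
            "key": list(self.key) if self.key else None,
            "n_draws": self.n_draws,
            "converged": self.converged,
            "rhat": self.rhat,
            "ess": self.ess,
            "effect": {"tau": list(self.effect.tau), "active": list(self.effect.active)},
            "config": {
                "n_chains": self.config.n_chains,
                "warmup": self.config.warmup,
                "stored_samples_total": self.config.stored_samples_total,
                "seed": self.config.seed,
                "n_walkers": self.config.n_walkers,
                "thin": self.config.thin,
            },
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# the model


class BivariateNormalModel:
    """Bivariate normal model of (HAZ, BAZ) for one subpopulation.

    Parameters
    ----------
    endog : (n, 2) array
        One row per child: (HAZ, BAZ).
    groups : (n,) array, optional
        Household labels; required when ``effect`` has an active
        component.
    effect : HouseholdEffect, optional
        Which outcomes carry a household random effect.  Default: none.
    key : (municipality, area), optional
        Carried through to results for reporting.
    """

    def __init__(self, endog, groups=None, effect: HouseholdEffect | None = None,
                 key: tuple[str, str] | None = None):
        self.endog = np.atleast_2d(np.asarray(endog, dtype=float))
        if self.endog.shape[1] != 2:
            raise ValueError("endog must have two columns (HAZ, BAZ)")
        if not np.all(np.isfinite(self.endog)):
            raise ValueError("endog contains non-finite values")
        self.effect = effect or HouseholdEffect.none()
        if groups is None:
            if self.effect.any_active:
                raise ValueError("household groups are required for a random-effect model")
            groups = np.arange(len(self.endog))
        self.groups = np.asarray(groups)
        if len(self.groups) != len(self.endog):
            raise ValueError("groups and endog must have equal length")
        self.key = key
        self._stats = _SuffStats.from_arrays(self.endog, self.groups)

    @classmethod
    def from_sample(cls, sample: SubpopulationSample,
                    effect: HouseholdEffect | None = None) -> "BivariateNormalModel":
        return cls(sample.y, groups=sample.household_index, effect=effect, key=sample.key)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, effect: HouseholdEffect | None = None,
                       key=None) -> "BivariateNormalModel":
        return cls(
            df[["haz", "baz"]].to_numpy(dtype=float),
            groups=df["household_id"].to_numpy() if "household_id" in df else None,
            effect=effect,
            key=key,
        )

    @property
    def nobs(self) -> int:
        return self._stats.n

    # -- likelihood / prior -------------------------------------------------

    def loglike(self, params: ModelParams, tau: tuple[float, float] | None = None) -> float:
        """Exact (marginal, when clustered) log-likelihood at one parameter point."""
        if abs(params.rho) >= 1.0:
            raise ValueError("rho must satisfy |rho| < 1 for a non-singular covariance")
        tau = tau if tau is not None else self.effect.tau
        return float(
            _loglike_batch(
                self._stats, self.effect.active,
                params.mu[0], params.mu[1], params.sigma[0], params.sigma[1], params.rho,
                tau[0], tau[1],
            )
        )

    def _unpack(self, x):
        """Unconstrained batch (..., ndim) -> natural-scale parameter arrays."""
        mu1, mu2 = x[..., 0], x[..., 1]
        s1 = np.exp(x[..., 2])
        s2 = np.exp(x[..., 3])
        rho = np.tanh(x[..., 4])
        j = 5
        tau1 = np.zeros_like(mu1)
        tau2 = np.zeros_like(mu1)
        if self.effect.active[0]:
            tau1 = np.exp(x[..., j])
            j += 1
        if self.effect.active[1]:
            tau2 = np.exp(x[..., j])
        return mu1, mu2, s1, s2, rho, tau1, tau2

    def _logpost_batch(self, x):
        """Unnormalized log-posterior on the unconstrained scale, walker-vectorized.

        Includes the Jacobians that make the priors flat in mu, log-flat in
        sigma, U(-1,1) in rho, and flat in tau on the natural scale.
        """
        x = np.asarray(x, dtype=float)
        bad = np.any(np.abs(x) > 40.0, axis=-1)  # guard exp overflow far outside support
        xs = np.where(bad[..., None], 0.0, x)
        mu1, mu2, s1, s2, rho, tau1, tau2 = self._unpack(xs)
        ll = _loglike_batch(self._stats, self.effect.active, mu1, mu2, s1, s2, rho, tau1, tau2)
        lp = np.log1p(-rho * rho)  # U(-1,1) prior via atanh transform
        j = 5
        if self.effect.active[0]:
            lp = lp + xs[..., j]   # flat prior on tau1 via log transform
            j += 1
        if self.effect.active[1]:
            lp = lp + xs[..., j]
        return np.where(bad, -np.inf, ll + lp)

    # -- maximum likelihood -------------------------------------------------

    def _mle_closed_form(self) -> ModelParams:
        st = self._stats
        cov = st.scatter / st.n
        s1 = float(np.sqrt(cov[0, 0]))
        s2 = float(np.sqrt(cov[1, 1]))
        if s1 <= 0 or s2 <= 0:
            raise ValueError("degenerate data: zero variance in an outcome")
        rho = float(cov[0, 1] / (s1 * s2))
        rho = float(np.clip(rho, -0.999999, 0.999999))
        return ModelParams(mu=(float(st.ybar[0]), float(st.ybar[1])), sigma=(s1, s2), rho=rho)

    def fit(self) -> BivariateMLResults:
        """Maximum-likelihood fit: closed form without a random effect, numeric with.

        The clustered fit maximizes the exact marginal likelihood with
        tau >= 0 allowed on the boundary; AIC counts 5 base parameters
        plus one per active tau.
        """
        base = self._mle_closed_form()
        if not self.effect.any_active:
            res = BivariateMLResults(
                model=self, params=base, effect=HouseholdEffect.none(),
                loglik=self.loglike(base, tau=(0.0, 0.0)), n_params=5,
            )
            res.bse = self._numeric_bse(res)
            return res

        active = self.effect.active

        def pack_nat(vec):
            mu = (vec[0], vec[1])
            sigma = (np.exp(vec[2]), np.exp(vec[3]))
            rho = np.tanh(vec[4])
            tau = [0.0, 0.0]
            j = 5
            for l in range(2):
                if active[l]:
                    tau[l] = vec[j]
                    j += 1
            return ModelParams(mu=mu, sigma=sigma, rho=rho), (tau[0], tau[1])

        def nll(vec):
            p, tau = pack_nat(vec)
            return -self.loglike(p, tau=tau)

        x0 = [base.mu[0], base.mu[1], np.log(base.sigma[0]), np.log(base.sigma[1]),
              np.arctanh(base.rho)]
        bounds = [(None, None)] * 5
        starts = []
        for tau0 in (0.1, 0.4):
            starts.append(x0 + [tau0] * self.effect.n_active)
        bounds += [(0.0, None)] * self.effect.n_active

        best = None
        ok = False
        for s0 in starts:
            r = minimize(nll, np.asarray(s0, dtype=float), method="L-BFGS-B", bounds=bounds)
            if best is None or r.fun < best.fun:
                best = r
            ok = ok or r.success
        params, tau = pack_nat(best.x)
        eff = HouseholdEffect(
            tau=(tau[0] if active[0] else 0.0, tau[1] if active[1] else 0.0), active=active
        )
        res = BivariateMLResults(
            model=self, params=params, effect=eff, loglik=-float(best.fun),
            n_params=5 + self.effect.n_active, converged=ok,
        )
        if not ok:
            warnings.warn(
                f"ML optimizer did not certify convergence for {self.key}; "
                "best iterate returned", ConvergenceWarning,
            )
        res.bse = self._numeric_bse(res)
        return res

    def _numeric_bse(self, res: BivariateMLResults) -> np.ndarray | None:
        """Standard errors from a central-difference observed information matrix."""
        active = res.effect.active
        theta = [*res.params.mu, *res.params.sigma, res.params.rho]
        theta += [res.effect.tau[l] for l in range(2) if active[l]]
        theta = np.asarray(theta, dtype=float)

        def nat_ll(v):
            try:
                tau = [0.0, 0.0]
                j = 5
                for l in range(2):
                    if active[l]:
                        tau[l] = v[j]
                        j += 1
                p = ModelParams(mu=(v[0], v[1]), sigma=(v[2], v[3]), rho=v[4])
                return self.loglike(p, tau=(tau[0], tau[1]))
            except (ValueError, FloatingPointError):
                return -np.inf

        k = len(theta)
        h = 1e-4 * np.maximum(1.0, np.abs(theta))
        H = np.empty((k, k))
        f0 = nat_ll(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                fpp = nat_ll(theta + ei + ej)
                fpm = nat_ll(theta + ei - ej)
                fmp = nat_ll(theta - ei + ej)
                fmm = nat_ll(theta - ei - ej)
                if not all(np.isfinite([fpp, fpm, fmp, fmm, f0])):
                    return None
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return None
        d = np.diag(cov)
        if np.any(d <= 0):
            return None
        return np.sqrt(d)

    # -- posterior sampling -------------------------------------------------

    def fit_bayes(self, config: MCMCConfig | None = None) -> PosteriorSamples:
        """Sample the posterior and return stored draws plus diagnostics.

        Refuses fewer than 3 children (the reference priors are improper
        and the posterior only becomes proper from n >= 3 with
        non-degenerate data); warns below 10.  Runs ``n_chains``
        independent ensembles seeded from ``config.seed``; identical
        config and seed reproduce identical draws.
        """
        config = config or MCMCConfig()
        n = self.nobs
        if n < 3:
            raise ValueError(
                f"posterior is improper with n={n} < 3 observations under reference priors"
            )
        if n < 10:
            warnings.warn(f"only n={n} children; posterior will be diffuse", UserWarning)

        ndim = 5 + self.effect.n_active
        nwalkers = max(config.n_walkers, 2 * ndim + 2)
        draws_per_chain = config.stored_samples_total // config.n_chains
        keep_steps = int(np.ceil(draws_per_chain / nwalkers))
        post_steps = config.thin * keep_steps

        base = self._mle_closed_form()
        center = np.array(
            [base.mu[0], base.mu[1], np.log(base.sigma[0]), np.log(base.sigma[1]),
             np.arctanh(np.clip(base.rho, -0.99, 0.99))]
            + [np.log(0.1)] * self.effect.n_active
        )

        chains_nat = []     # per chain: (draws_per_chain, k) natural-scale draws
        diag_chains = []    # per chain: (nwalkers, post_steps, k) for diagnostics
        for c in range(config.n_chains):
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(c,))
            s_init, s_mcmc = ss.generate_state(2) & 0x7FFFFFFF
            rs = np.random.RandomState(s_init)
            init = center + 0.05 * rs.standard_normal(size=(nwalkers, ndim))
            moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
            sampler = emcee.EnsembleSampler(nwalkers, ndim, self._logpost_batch,
                                            vectorize=True, moves=moves)
            sampler.random_state = np.random.RandomState(s_mcmc).get_state()
            sampler.run_mcmc(init, config.warmup + post_steps, progress=False)
            raw = sampler.get_chain(discard=config.warmup)      # (post_steps, nw, ndim)
            nat = self._natural_draws(raw)                      # (post_steps, nw, k)
            diag_chains.append(np.swapaxes(nat, 0, 1))
            thinned = nat[config.thin - 1::config.thin]         # (keep_steps, nw, k)
            flat = thinned.reshape(-1, nat.shape[-1])[:draws_per_chain]
            chains_nat.append(flat)

        draws = np.concatenate(chains_nat, axis=0)
        chain_ix = np.repeat(np.arange(config.n_chains), draws_per_chain)
        names = self._param_names()
        rhat, ess = self._diagnostics(
            np.stack(chains_nat, axis=0), np.concatenate(diag_chains, axis=0), names
        )
        converged = all(np.isfinite(v) and v <= 1.01 for v in rhat.values())
        if not converged:
            worst = max(rhat, key=lambda k: rhat[k])
            warnings.warn(
                f"split-R-hat above 1.01 for {self.key or 'sample'} "
                f"(worst: {worst}={rhat[worst]:.4f}); treat results with caution",
                ConvergenceWarning,
            )

        tau = None
        if self.effect.any_active:
            tau = np.zeros((len(draws), 2))
            j = 5
            for l in range(2):
                if self.effect.active[l]:
                    tau[:, l] = draws[:, j]
                    j += 1
        return PosteriorSamples(
            mu=draws[:, 0:2].copy(),
            sigma=draws[:, 2:4].copy(),
            rho=draws[:, 4].copy(),
            tau=tau,
            chain=chain_ix,
            effect=self.effect,
            config=config,
            rhat=rhat,
            ess=ess,
            converged=converged,
            key=self.key,
        )

    def _natural_draws(self, raw: np.ndarray) -> np.ndarray:
        out = raw.copy()
        out[..., 2] = np.exp(raw[..., 2])
        out[..., 3] = np.exp(raw[..., 3])
        out[..., 4] = np.tanh(raw[..., 4])
        for j in range(5, raw.shape[-1]):
            out[..., j] = np.exp(raw[..., j])
        return out

    def _param_names(self) -> list[str]:
        names = ["mu_haz", "mu_baz", "sigma_haz", "sigma_baz", "rho"]
        if self.effect.active[0]:
            names.append("tau_haz")
        if self.effect.active[1]:
            names.append("tau_baz")
        return names

    @staticmethod
    def _diagnostics(stored_chains: np.ndarray, walker_chains: np.ndarray,
                     names: list[str]):
        """Split-R-hat and bulk ESS per parameter.

        R-hat compares the independent ensemble runs (the stored, thinned
        per-chain draws); ESS is computed on the unthinned walker-level
        chains so it reflects the sampler's true autocorrelation.
        """
        import arviz as az

        rhat, ess = {}, {}
        for j, name in enumerate(names):
            rhat[name] = float(az.rhat(stored_chains[:, :, j]))
            ess[name] = float(az.ess(walker_chains[:, :, j]))
        return rhat, ess


# ---------------------------------------------------------------------------
# functional surface


def log_likelihood(params: ModelParams, effect: HouseholdEffect,
                   sample: SubpopulationSample) -> float:
    """Exact log-likelihood of one subpopulation (marginal when clustered)."""
    if sample.n_children == 0:
        raise ValueError("empty sample")
    model = BivariateNormalModel.from_sample(sample, effect=effect)
    return model.loglike(params, tau=effect.tau)


def log_prior(params: ModelParams) -> float:
    """Reference log-prior density up to a constant, on the natural scale.

    Flat in mu, pi(sigma) ~ 1/sigma on each SD, uniform on rho over
    (-1, 1); -inf outside the support.
    """
    if params.sigma[0] <= 0 or params.sigma[1] <= 0 or not -1 < params.rho < 1:
        return -np.inf
    return float(-np.log(params.sigma[0]) - np.log(params.sigma[1]))


def fit_posterior(sample: SubpopulationSample, effect: HouseholdEffect | None = None,
                  config: MCMCConfig | None = None) -> PosteriorSamples:
    """Posterior sampling for one subpopulation (see BivariateNormalModel.fit_bayes)."""
    return BivariateNormalModel.from_sample(sample, effect=effect).fit_bayes(config)


def fit_ml(sample: SubpopulationSample,
           effect: HouseholdEffect | None = None) -> BivariateMLResults:
    """Maximum-likelihood fit for one subpopulation (see BivariateNormalModel.fit)."""
    return BivariateNormalModel.from_sample(sample, effect=effect).fit()


def marginal_params(params: ModelParams, effect: HouseholdEffect) -> ModelParams:
    """Marginalize the household effect: Sigma -> Sigma_w + Sigma.

    Marginal SDs are sqrt(sigma_l^2 + tau_l^2); the marginal correlation
    rescales the conditional covariance by the inflated SDs.  Identity
    when tau = 0, making fits with and without random effects directly
    comparable.
    """
    t1, t2 = effect.tau
    if t1 == 0.0 and t2 == 0.0:
        return params
    s1 = float(np.hypot(params.sigma[0], t1))
    s2 = float(np.hypot(params.sigma[1], t2))
    rho = float(params.rho * params.sigma[0] * params.sigma[1] / (s1 * s2))
    return ModelParams(mu=params.mu, sigma=(s1, s2), rho=rho)
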