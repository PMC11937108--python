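"""Per-outcome selection of household random effects via likelihood-ratio tests.

Before the bivariate model is fitted, each subpopulation is screened —
separately for HAZ and BAZ — for household-level dependency: a
univariate normal (mean, variance) is compared against a univariate
normal with an additive household random intercept, both fitted by
maximum likelihood on the exact marginal likelihood.  The random effect
is retained when the likelihood-ratio test is significant at the 10%
level AND the AIC favors it.

The LRT statistic is referred to chi-square with 1 df by default.  The
variance component sits on the boundary of its parameter space under
the null, which makes the naive chi-square(1) reference conservative;
the 50:50 mixture chi2_0:chi2_1 correction is available via
``boundary_mixture=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .data import SubpopulationSample
from .model import HouseholdEffect

__all__ = ["ModelSelectionResult", "lrt_random_effect", "select_models"]

_LOG_2PI = np.log(2.0 * np.pi)

OUTCOME_COLUMNS = {"haz": 0, "baz": 1}


@dataclass(frozen=True)
class ModelSelectionResult:
    municipality: str
    area: str
    outcome: str
    loglik_null: float
    loglik_re: float
    lrt_stat: float
    p_value: float
    aic_null: float
    aic_re: float
    selected_re: bool
    tau_hat: float = 0.0
    reason: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.municipality, self.area)


@dataclass(frozen=True)
class _UniStats:
    """Sufficient statistics of one outcome for the clustered normal likelihood."""

    n: int
    mean: float
    ss: float                 # total centered sum of squares
    n_households: int
    ssw: float                # within-household sum of squares
    sizes: np.ndarray
    size_counts: np.ndarray
    size_means: np.ndarray
    size_ss: np.ndarray       # centered SS of household means, per size
    log_size_jacobian: float  # -(1/2) sum_h log s_h (household-mean transform)

    @classmethod
    def from_arrays(cls, y: np.ndarray, households: np.ndarray) -> "_UniStats":
        y = np.asarray(y, dtype=float)
        n = len(y)
        codes = np.unique(households, return_inverse=True)[1]
        H = codes.max() + 1
        counts = np.bincount(codes, minlength=H).astype(float)
        hmeans = np.bincount(codes, weights=y, minlength=H) / counts
        ssw = float(np.sum((y - hmeans[codes]) ** 2))
        sizes = np.unique(counts).astype(int)
        mcounts, mmeans, mss = [], [], []
        for s in sizes:
            b = hmeans[counts == s]
            mcounts.append(len(b))
            mmeans.append(b.mean())
            mss.append(float(np.sum((b - b.mean()) ** 2)))
        return cls(
            n=n, mean=float(y.mean()), ss=float(np.sum((y - y.mean()) ** 2)),
            n_households=int(H), ssw=ssw, sizes=sizes,
            size_counts=np.array(mcounts, dtype=float),
            size_means=np.array(mmeans), size_ss=np.array(mss),
            log_size_jacobian=float(-0.5 * np.sum(np.log(counts))),
        )


def _loglik_re(stats: _UniStats, mu: float, var: float, tau2: float) -> float:
    n_con = stats.n - stats.n_households
    ll = -0.5 * n_con * (_LOG_2PI + np.log(var)) - stats.ssw / (2.0 * var) \
        + stats.log_size_jacobian
    for i, s in enumerate(stats.sizes):
        c = tau2 + var / s
        m = stats.size_counts[i]
        dev = stats.size_ss[i] + m * (stats.size_means[i] - mu) ** 2
        ll += -0.5 * m * (_LOG_2PI + np.log(c)) - dev / (2.0 * c)
    return float(ll)


def _profile_mu_var(stats: _UniStats, tau2: float) -> float:
    """Maximized log-likelihood at fixed tau2 (inner optimization over mu, var)."""

    def neg_profile(logvar):
        var = np.exp(logvar)
        # optimal mu at fixed variances: precision-weighted household means
        w = stats.size_counts / (tau2 + var / stats.sizes)
        mu = float(np.sum(w * stats.size_means) / np.sum(w))
        return -_loglik_re(stats, mu, var, tau2)

    v0 = stats.ss / stats.n
    res = minimize_scalar(neg_profile, bracket=(np.log(v0) - 2.0, np.log(v0)),
                          method="brent", options={"xtol": 1e-10})
    return -float(res.fun)


def lrt_random_effect(
    sample: SubpopulationSample,
    outcome: str,
    alpha: float = 0.10,
    boundary_mixture: bool = False,
) -> ModelSelectionResult:
    """Test one outcome of one subpopulation for a household random intercept.

    Requires at least two households and at least one household with two
    or more children; otherwise the variance component is unidentifiable
    and the no-effect model is kept with an explanatory reason.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")
    y = sample.y[:, OUTCOME_COLUMNS[outcome]]
    stats = _UniStats.from_arrays(y, sample.household_index)

    if stats.ss <= 0:
        raise ValueError(f"degenerate data: zero variance of {outcome} in {sample.key}")

    var0 = stats.ss / stats.n
    ll0 = -0.5 * stats.n * (_LOG_2PI + np.log(var0) + 1.0)
    aic0 = 2.0 * 2 - 2.0 * ll0

    if stats.n_households < 2 or np.all(stats.sizes < 2):
        return ModelSelectionResult(
            municipality=sample.municipality, area=sample.area, outcome=outcome,
            loglik_null=ll0, loglik_re=ll0, lrt_stat=0.0, p_value=1.0,
            aic_null=aic0, aic_re=aic0 + 2.0, selected_re=False,
            reason="re_unidentifiable: no multi-child household",
        )

    # outer 1-d search over tau^2 >= 0 with profiled (mu, var)
    v0 = var0

    def neg_outer(u):  # tau2 = exp(u) parametrization for the interior search
        return -_profile_mu_var(stats, np.exp(u))

    ll_boundary = _profile_mu_var(stats, 0.0)
    grid = np.log(v0) + np.array([-6.0, -4.0, -2.0, -1.0, 0.0, 1.0])
    vals = [-neg_outer(u) for u in grid]
    best = int(np.argmax(vals))
    lo = grid[max(0, best - 1)]
    hi = grid[min(len(grid) - 1, best + 1)]
    res = minimize_scalar(neg_outer, bounds=(lo - 1.0, hi + 1.0), method="bounded",
                          options={"xatol": 1e-8})
    ll_interior = -float(res.fun)
    if ll_interior >= ll_boundary:
        ll1 = ll_interior
        tau_hat = float(np.sqrt(np.exp(res.x)))
    else:
        ll1 = ll_boundary
        tau_hat = 0.0

    lrt = 2.0 * (ll1 - ll0)
    if lrt < -1e-6:
        raise RuntimeError(f"negative LRT statistic {lrt}: optimizer failure")
    lrt = max(lrt, 0.0)
    if boundary_mixture:
        p = 0.5 * chi2.sf(lrt, 1) + (0.5 if lrt <= 0 else 0.0)
    else:
        p = float(chi2.sf(lrt, 1))
    aic1 = 2.0 * 3 - 2.0 * ll1
    return ModelSelectionResult(
        municipality=sample.municipality, area=sample.area, outcome=outcome,
        loglik_null=ll0, loglik_re=ll1, lrt_stat=lrt, p_value=float(p),
        aic_null=aic0, aic_re=aic1,
        selected_re=bool(p < alpha and aic1 < aic0),
        tau_hat=tau_hat,
    )


def select_models(
    samples: list[SubpopulationSample],
    alpha: float = 0.10,
    boundary_mixture: bool = False,
) -> tuple[dict[tuple[str, str], HouseholdEffect], list[ModelSelectionResult]]:
    """Run both per-outcome tests on every subpopulation.

    Returns the per-subpopulation HouseholdEffect (active flags set
    exactly where the test selected the random effect, tau initialized
    at the univariate ML estimate) and the full list of test results for
    the selection report.
    """
    effects: dict[tuple[str, str], HouseholdEffect] = {}
    results: list[ModelSelectionResult] = []
    for sample in samples:
        per_outcome = {}
        for outcome in ("haz", "baz"):
            r = lrt_random_effect(sample, outcome, alpha=alpha,
                                  boundary_mixture=boundary_mixture)
            per_outcome[outcome] = r
            results.append(r)
        active = (per_outcome["haz"].selected_re, per_outcome["baz"].selected_re)
        tau = (
            per_outcome["haz"].tau_hat if active[0] else 0.0,
            per_outcome["baz"].tau_hat if active[1] else 0.0,
        )
        effects[sample.key] = HouseholdEffect(tau=tau, active=active)
    return effects, results
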