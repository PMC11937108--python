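# Methods

## Model

Each subpopulation (one municipality × rural/urban cell) contributes
children indexed k with outcome pairs Y_k = (HAZ_k, BAZ_k), modelled as
bivariate normal MVN(mu, Sigma) with Sigma parametrized by the two
standard deviations (s1, s2) and the correlation rho.  The latent DBM
prevalence is the probability mass of the "stunted and overweight"
rectangle, p = Pr(Y1 < t1, Y2 > t2), with default cutoffs t1 = −2 (HAZ)
and t2 = +2 (BAZ).  Both classification inequalities are strict: a
z-score exactly at a cutoff is not a case.  The rectangle probability
is evaluated as Phi(u1) − Phi2(u1, u2; rho), where the standard
bivariate normal CDF Phi2 is computed from Owen's T function
(`scipy.special.owens_t`), which is accurate to near machine precision;
rho = ±1 inputs are evaluated as their analytic comonotone/antithetic
limits rather than clamped.  Note that for parameter points whose true
rectangle probability is below ~1e−13 the subtraction hits the
double-precision cancellation floor and the result underflows to 0.

### Household random effects

Children of one household h may share an additive deviation
W_h ~ MVN(0, Sigma_w) with *diagonal* Sigma_w = diag(tau1², tau2²); a
single active component makes W_h effectively unidimensional.  The
marginal law is MVN(mu, Sigma_w + Sigma) with equicorrelated household
blocks.  The clustered likelihood is evaluated exactly, not by Monte
Carlo: conditional on the household, within-household contrasts depend
only on Sigma, while the household mean of a size-s household is
MVN(mu, Sigma_w + Sigma/s).  Transforming each household block to
(mean, orthonormal contrasts) carries a Jacobian of −(d/2)·log s per
household (d = 2 outcomes), and the whole likelihood reduces to
sufficient statistics: the total within-household scatter plus, per
distinct household size, the count, mean and scatter of household
means.  This makes a likelihood evaluation O(#distinct sizes)
regardless of n, which is what keeps the replicated calibration studies
cheap.  A dense-covariance construction over all children serves as the
test oracle for this factorization.

After fitting, random-effect models are re-parametrized to their
marginal form: SDs sqrt(s_l² + tau_l²) and correlation
rho·s1·s2 / (sqrt(s1²+tau1²)·sqrt(s2²+tau2²)), the identity when
tau = 0, so that all subpopulations are summarized on the same scale
and the rectangle probability always refers to a child drawn at random
from the population of households.

## Priors and sampling

Priors are the reference choice: flat on mu, log-flat on each SD
(pi(sigma) ∝ 1/sigma), uniform on rho over (−1, 1), and — when a random
effect is active — flat on tau ≥ 0 (the paperless-parameter choice
here; a boundary-friendly improper uniform on the SD scale).  These
priors are improper; the posterior is proper from n ≥ 3 with
non-degenerate data, and the implementation refuses smaller samples
rather than sample an improper posterior (it warns below n = 10).

Sampling runs on the unconstrained scale (mu, log sigma, atanh rho,
log tau) with the exact Jacobian terms, so the stated priors hold on
the natural scale.  The sampler is the affine-invariant ensemble
sampler (emcee) with an 80:20 mixture of differential-evolution and
snooker moves — a robust gradient-free choice that mixes well on this
smooth 5–7 dimensional posterior.  Defaults: 4 independent ensembles
("chains") of 16 walkers, 1,000 warmup steps each, post-warmup draws
thinned by 3 and pooled to exactly M = 20,000 stored draws (M matches
the analysis standard and gives stable 3-decimal exceedance
probabilities).  Walkers are initialized in a tight ball around the
closed-form MLE.  The `target_accept` configuration field is inert for
this sampler and retained for step-size-tuned alternatives.

Diagnostics: split-R-hat is computed between the independent ensemble
runs on the stored draws; effective sample sizes are computed on the
unthinned walker-level chains so they reflect the sampler's true
autocorrelation.  Any parameter with R-hat > 1.01 raises a
`ConvergenceWarning` and flags the results object and the pipeline
summary row — never silent.  At the default budget the survey-scale
fits reach R-hat ≤ 1.01 and ESS in the thousands; heavily reduced
budgets (as in some tests) may trip the flag without invalidating
calibration-level summaries.

Determinism: one root seed drives everything.  Chains derive seeds via
`SeedSequence(seed, spawn_key=(chain,))`; the pipeline derives one seed
per subpopulation from the run seed and a CRC-32 of the
"area_municipality" label, and the generator uses
`SeedSequence(seed, spawn_key=(crc32("municipality|area"),))`, so
adding or removing a subpopulation never shifts another's draws.

## Model selection

Household dependency is screened per subpopulation × outcome on the
univariate normal versus normal-plus-household-intercept pair, fitted
by exact marginal ML (profile search over tau², with the inner
(mu, variance) problem solved by a 1-d Brent pass over log variance and
precision-weighted means).  The decision rule requires both a
likelihood-ratio p-value below alpha = 0.10 AND a lower AIC for the
random-effect model; the LRT statistic is referred to chi-square(1).
Because tau = 0 lies on the boundary of the parameter space, the naive
chi-square(1) reference is conservative (empirical size ~4–6% at a 10%
nominal level in the packaged null simulations); the 50:50
chi2_0:chi2_1 boundary mixture is available via `boundary_mixture=True`
but is not the default, keeping the selection criterion at its plain
reading.  No multiple-testing adjustment is applied across the 8 × 2
tests.  The bivariate fit then activates tau components exactly where
selected, with the unselected component pinned at zero.

## Synthetic-data generator

The generator emulates the motivating survey: eight subpopulations
(four municipalities × rural/urban) with the published household counts
(27–91 per cell) and children-per-household ratios (1.2–1.8).
Household sizes are drawn from a distribution over {1, 2, 3} children
matching each cell's ratio in expectation (a small fixed 3-child mass —
5% when the ratio ≥ 1.5, else 2% — with the 1/2-child split solving for
the mean); only the mean is constrained by the survey's descriptive
tables.  Default z-score parameters were chosen once to reproduce the
published posterior landscape — rural HAZ means below urban ones, BAZ
means above zero, HAZ SDs near or above 1, negative HAZ–BAZ correlation
in rural Ipixuna/Jutai and positive elsewhere — with implied latent DBM
prevalences between ~0.1% and ~3.2% (rural Jutai highest).  Household
random effects are active by default for HAZ in urban Jutai
(tau1 = 0.6) and BAZ in urban Ipixuna (tau2 = 0.5), the pattern the
survey analysis selected; the magnitudes are chosen for detectability
at the survey's sample sizes, since no within-household correlation
magnitudes were published.  Ages are uniform over 6–59 months.

`table1_cohort()` is a separate, fully deterministic stand-in that
reproduces the survey's *bookkeeping* exactly — 585 children, 422
households, per-cell counts, ratios and observed DBM cases — using
placeholder z-scores ((0,0) for non-cases, (−3,3) for cases).  It
carries no distributional information and exists only for descriptive
reporting checks.

What the generator does not emulate: non-normal tails or skewness in
real z-scores, age structure in the outcomes, informative sampling,
seasonality, or covariates.  Tests passing on these cohorts therefore
certify the estimator under its own assumptions, not robustness to
their violation.

## Numerical choices and test scales

* Closed-form MLE (mean, covariance with 1/n denominator) for the
  independence model; L-BFGS-B on the exact marginal likelihood with
  tau bounded at 0 (two tau starts, 0.1 and 0.4) for clustered ML.
  AIC counts 5 base parameters plus one per active tau.
* Standard errors for ML results come from a central-difference
  observed information matrix on the natural scale; they are reported
  as NaN when the information is not invertible (e.g. tau exactly on
  the boundary).
* Plausibility filtering is inclusive at the bounds (HAZ in [−6, 6],
  BAZ in [−5, 5] kept); missing z-scores are excluded with explicit
  `haz_missing`/`baz_missing` reason codes; a record failing several
  checks carries the first reason in the documented priority order.
* Display rounding (half-up, 1 decimal for percentages/ratios,
  3 decimals for probabilities) happens only in the report layer.
* Replicated studies use reduced but calibrated MCMC budgets
  (2 chains × 800 warmup, 4,000 stored draws for the 200-replicate
  coverage study; 500/200 replicates for the selection size/power
  study) — sizes chosen so each study completes in a few minutes while
  keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* The bivariate normal is an approximation; real anthropometry can be
  skewed or heavy-tailed, and the latent prevalence inherits any
  misfit in the joint tails.
* Correlations are estimated freely per subpopulation; a
  constant-correlation variant is not implemented.
* Sigma_w is diagonal: no cross-outcome household correlation.
* The LRT reference distribution at the boundary makes default
  selection conservative; published selection decisions based on other
  references may differ for borderline cases.
* Posterior results at very small n (< 10) are dominated by the
  improper priors' tails and are flagged, not forbidden.
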