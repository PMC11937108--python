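# latentdbm

Bayesian latent estimation of the individual-level **double burden of
malnutrition (DBM)** — the co-occurrence of stunting and overweight in
the same child — for small rural and urban subpopulations.

## The problem

In surveys of children aged 6–59 months, stunting is defined as a
height-for-age z-score (HAZ) below −2 and overweight as a BMI-for-age
z-score (BAZ) above +2, both relative to the WHO growth reference.  The
conventional estimate of DBM prevalence counts children who are both,
which collapses to 0% whenever a small sample happens to contain no
cases — even in populations where the joint distribution of the two
indicators clearly carries double-burden risk.  This package estimates
the **latent** DBM prevalence instead: within each subpopulation the
pair (HAZ, BAZ) is modelled as bivariate normal,

    Y_k ~ MVN(mu, Sigma),   Sigma = [[s1^2, rho*s1*s2], [rho*s1*s2, s2^2]],

and the latent prevalence is the rectangle probability

    p = Pr(Y1 < t1, Y2 > t2 | theta) = Phi(u1) - Phi2(u1, u2; rho),

with u1 = (t1 − mu1)/s1, u2 = (t2 − mu2)/s2, t1 = −2, t2 = +2.  Priors
are flat on the means, log-flat on the standard deviations and uniform
on the correlation; the posterior is sampled by MCMC (20,000 stored
draws by default) and every draw is pushed through the rectangle
probability, yielding the posterior distribution of p: its median,
equal-tailed 95% credible interval, exceedance probabilities
Pr(p > 1%) and Pr(p > 3%), and Pr(rho > 0).  Children from the same
household can share an additive bivariate random effect
W_h ~ MVN(0, diag(tau^2)); whether to include it is decided per
subpopulation and per outcome by a likelihood-ratio test (10% level)
combined with AIC, and random-effect fits are re-parametrized to their
marginal form MVN(mu, diag(tau^2) + Sigma) for comparability.

Because the motivating survey data (585 children in 422 households
across four Amazonas municipalities, 2015–16) are not publicly
deposited, the package ships a seeded synthetic-cohort generator with
the same design scale and statistical structure, used by every test.

## Worked example

```python
import latentdbm as ldbm

truth = ldbm.default_study_truth(seed=1)         # 8 subpopulations, survey scale
cohort, manifest = ldbm.generate_study(truth)

kept, excluded = ldbm.filter_plausible(cohort)
sample = [s for s in ldbm.group_by_subpopulation(kept)
          if s.key == ("Jutai", "rural")][0]
print(sample.n_children, sample.n_households)    # 74 42  (varies with the seed)

model = ldbm.BivariateNormalModel.from_sample(sample)
draws = model.fit_bayes(ldbm.MCMCConfig(seed=1))
print(draws.summary().round(3))
summary = ldbm.summarize_ldbm(draws)
print(round(summary.median, 3), (round(summary.ci_low, 3), round(summary.ci_high, 3)))
print({c: round(v, 3) for c, v in summary.exceedance.items()})
```

With this seed the posterior parameter table reports, e.g., a HAZ mean
of −1.139 (sd 0.120) and a correlation of −0.311 (sd 0.096), all with
split-R-hat 1.001 and effective sample sizes near 3,000; the
latent-prevalence summary prints a median of `0.02` with 95% interval
`(0.008, 0.044)` and exceedance probabilities `{0.01: 0.945,
0.03: 0.161}` — i.e. a ~94% posterior probability that more than 1% of
children in this subpopulation carry both conditions, from a sample of
74.  Exact numbers vary with the simulation seed.

The same analysis end-to-end from a shell:

```sh
latentdbm simulate --seed 1 --out study/
latentdbm run --input study/cohort.csv --out results/ --seed 1 --exceedance 0.01,0.03
```

which writes `excluded.csv`, `selection.csv`, `descriptive.csv`,
per-subpopulation posterior draws, `ldbm_summary.csv` and `run.log`.

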