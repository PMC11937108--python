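import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import latentdbm as ldbm

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """Deterministic synthetic cohort reproducing the survey bookkeeping."""
    return ldbm.table1_cohort()


@pytest.fixture(scope="session")
def rural_jutai_truth():
    """Survey-scale truth for the largest rural subpopulation (n ~ 74, 42 households)."""
    return ldbm.SubpopTruth(
        mu=(-1.45, 0.70), sigma=(1.20, 0.80), rho=-0.35,
        n_households=42, children_per_household={1: 0.25, 2: 0.70, 3: 0.05},
    )


@pytest.fixture()
def quick_mcmc():
    """Reduced sampling budget for smoke tests (not for calibration checks)."""
    return ldbm.MCMCConfig(n_chains=2, warmup=400, stored_samples_total=2000, thin=2, seed=0)


@pytest.fixture(scope="session")
def fitted_sample(rural_jutai_truth):
    """One synthetic subpopulation with a converged full-length posterior fit."""
    df = ldbm.generate_subpopulation(rural_jutai_truth, "Jutai", "rural", seed=3)
    sample = ldbm.group_by_subpopulation(df)[0]
    config = ldbm.MCMCConfig(n_chains=2, warmup=800, stored_samples_total=4000, thin=4, seed=9)
    draws = ldbm.fit_posterior(sample, config=config)
    return sample, draws


def make_sample(df):
    samples = ldbm.group_by_subpopulation(df)
    assert len(samples) == 1
    return samples[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
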