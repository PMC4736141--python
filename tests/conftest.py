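import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from spermarche import (  # noqa: E402
    MCMCConfig,
    experiment1_config,
    simulate_cohort,
    table_fixture,
)


@pytest.fixture(scope="session")
def exp1_fixture():
    return table_fixture("experiment1")


@pytest.fixture(scope="session")
def exp2_fixture():
    return table_fixture("experiment2")


@pytest.fixture(scope="session")
def sim_cohort():
    """One seeded on-farm style cohort at the generating truth, no scrotal
    offset, reused across tests that only need plausible data."""
    return simulate_cohort(experiment1_config(seed=42, in_vivo_offset_cm=0.0))


@pytest.fixture()
def light_mcmc():
    """Short but convergent sampler settings for single-fit unit tests."""
    return MCMCConfig(n_chains=2, n_iterations=6000, n_burnin=2000, seed=7)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Unit tests on tiny chains may trip the R-hat warning; the flag on
    the result is what tests assert on."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
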