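import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trajmix as tm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort() -> tm.SimulatedCohort:
    """A 120-subject draw from the default 4-group scenario."""
    return tm.simulate_cohort(tm.default_cohort_scenario(seed=11, n_subjects=120))


@pytest.fixture(scope="session")
def small_centered(small_cohort) -> tm.CenteredPanel:
    return tm.center_trajectories(small_cohort.panel)


@pytest.fixture(scope="session")
def small_fit_k2(small_centered) -> tm.FitResult:
    """A quick covariate-free K=2 fit reused across association tests."""
    return tm.fit_em(small_centered, K=2, cov_kind="independence", seed=5, n_starts=4)
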