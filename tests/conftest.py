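import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import icebears as ib

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return ib.make_grid(20, 20, 25.0, seed=1)


@pytest.fixture(scope="session")
def cov(grid):
    return ib.make_covariates(grid, 10, seed=2)


@pytest.fixture(scope="session")
def scenario():
    return ib.SimScenario(seed=7)


@pytest.fixture(scope="session")
def survey(grid, cov, scenario):
    data, truth = ib.simulate_survey(grid, cov, scenario, return_truth=True)
    return data, truth


@pytest.fixture(scope="session")
def smooth_spec(cov):
    return ib.build_smooths(cov)


@pytest.fixture(scope="session")
def default_fit(grid, cov, survey, smooth_spec):
    """One full joint fit on the reference synthetic survey (g0 = 1)."""
    data, _ = survey
    return ib.laplace_fit(data, grid, cov, smooth_spec, g0=1.0)


@pytest.fixture(scope="session")
def small_grid():
    return ib.make_grid(6, 6, 25.0, seed=3)


@pytest.fixture(scope="session")
def small_cov(small_grid):
    return ib.make_covariates(small_grid, 3, seed=4)
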