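import numpy as np
import pytest

from swip import (
    DEFAULT_TRUE_PARAMS,
    McmcConfig,
    SimCondition,
    generate_database,
    generate_focal,
)
from swip.study_runner import ALL_ARMS, grid_corner_conditions, run_condition


@pytest.fixture(scope="session")
def true_params():
    return DEFAULT_TRUE_PARAMS


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_condition():
    return SimCondition(
        K=5, delta_N=-100, delta_mu=0.5, tau2=0.05, n_reps=3, seed=202
    )


@pytest.fixture(scope="session")
def small_focal(true_params):
    return generate_focal(true_params, 11)


@pytest.fixture(scope="session")
def small_db(small_condition, true_params):
    return generate_database(small_condition, true_params, 12)


@pytest.fixture(scope="session")
def scaled_study(true_params):
    """Scaled-down rerun of the simulation study shared by several tests.

    Eight conditions spanning the design-grid corners, five
    replications each, all four analysis arms, with the study's sampler
    settings (4 chains of 2,000 iterations, 1,000 burn-in).
    """
    conditions = grid_corner_conditions(n_reps=5, base_seed=101)
    mcmc = McmcConfig(chains=4, iterations=2000, warmup=1000, rhat_threshold=1.02)
    return [
        run_condition(cond, true_params, arms=ALL_ARMS, mcmc=mcmc)
        for cond in conditions
    ]
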