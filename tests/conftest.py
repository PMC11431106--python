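import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import patsep as ps

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def estimator_cfg():
    return ps.EstimatorConfig()


@pytest.fixture(scope="session")
def dtheta_result():
    """Default correlation sweep (eta1 = eta2 = 0.5, 21 points, 10 trials)."""
    spec = ps.build_dtheta_sweep(0.5, grid_size=21, n_trials=10, seed=1)
    return ps.run_sweep(spec)


@pytest.fixture(scope="session")
def deta_result():
    """Default neuron-2 rate sweep (eta1 = 0.5, 17 points, 10 trials)."""
    spec = ps.build_deta_sweep(0.5, 17, n_trials=10, seed=2)
    return ps.run_sweep(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
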