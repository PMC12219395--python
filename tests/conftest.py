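import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_params():
    from antcargo import ModelParams

    return ModelParams()


@pytest.fixture(scope="session")
def short_trajectory(default_params):
    """One short default-parameter trajectory, shared across tests."""
    from antcargo.microsim import run_trial

    return run_trial(default_params, T_total=30.0, seed=11)
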