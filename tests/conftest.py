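import numpy as np
import pytest

from lymphsim.params import SimParams


@pytest.fixture(scope="session")
def default_params() -> SimParams:
    return SimParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_run():
    """One short interacting simulation shared across tests."""
    from lymphsim.engine import run_simulation
    params = SimParams(n_steps=4000, chi=1.0, seed=7, record_stride=10)
    return run_simulation(params)
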