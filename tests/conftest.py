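import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_log():
    """A short control-model log (n=4) used by network-construction tests."""
    from elnet.simulate import SimulationConfig, run_simulation

    cfg = SimulationConfig(n=4, steps=60, burn_in=0, model="control", mu=0.3,
                           seed=99)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def el_log():
    """One EL trial at n=6, long enough for a measured window."""
    from elnet.simulate import SimulationConfig, run_simulation

    cfg = SimulationConfig(n=6, steps=400, seed=7)
    return run_simulation(cfg)
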