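import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from socgaze import DetectionConfig, SampleStream
from socgaze.simulate import SimulationConfig

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20171018)


@pytest.fixture
def config():
    return DetectionConfig()


@pytest.fixture
def sim_config():
    """Small, noise-free-ish cohort config for fast deterministic tests."""
    return SimulationConfig(seed=7, n_participants=4, trials_per_condition=6,
                            blink_rate_per_trial=0.0)


def make_stream(x, y, valid=None, rate=500.0):
    """Stream at the nominal rate from position arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    t = np.arange(n) * (1000.0 / rate)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    return SampleStream(t=t, x=np.where(valid, x, np.nan),
                        y=np.where(valid, y, np.nan), valid=valid,
                        nominal_rate=rate)


@pytest.fixture
def steady_fixation_stream():
    """5000 ms of perfectly steady fixation at the screen center."""
    n = 2500
    return make_stream(np.zeros(n), np.zeros(n))
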