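import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_threshold():
    """Uniform threshold map at dark mean + 4 dark sigmas (default dark model)."""

    def make(shape=(64, 64), dark_mean=100.0, dark_sd=4.0, sigma=4.0):
        return np.full(shape, dark_mean + sigma * dark_sd)

    return make
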