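import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_profiles():
    """Three small villages for fast pipeline tests."""
    from ocprisk.cohort import DEFAULT_PROFILES
    from dataclasses import replace

    return tuple(replace(p, n_individuals=8) for p in DEFAULT_PROFILES[:3])
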