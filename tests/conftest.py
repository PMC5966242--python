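import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import deathfluct as df

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def growth_profile():
    """Single-interval no-death profile, desk scale."""
    return df.GrowthProfile((0.0, 24.0), (100.0, 1e5), (0.0,))


@pytest.fixture
def death_profile():
    """Single-interval profile with substantial death (d = 0.8)."""
    return df.GrowthProfile((0.0, 24.0), (100.0, 1e5), (0.8,))


@pytest.fixture
def tiny_profile():
    """Small instance usable by the event-by-event oracle."""
    return df.GrowthProfile((0.0, 5.0), (5.0, 50.0), (0.5,))
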