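import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from interpuq.paths import Path

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def peak3() -> Path:
    """Generic three-point fixture: a rise followed by a partial fall.

    Three measured points admit no sign alternation, so the reference
    inflexion count is 0 and plausible interpolations must keep a single
    curvature sign.
    """
    return Path([0.0, 1.0, 2.0], [0.0, 1.0, 0.5])


@pytest.fixture
def wiggle4() -> Path:
    """Four-point fixture with one inflexion (gradient-change signs -, +)."""
    return Path([0.0, 1.0, 2.0, 3.0], [0.0, 2.0, 3.0, 5.0])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
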