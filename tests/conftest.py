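import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vesselquant as vq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cylinder6():
    """Straight vertical cylinder, radius 6 mm, length 60 mm, 1 mm grid."""
    return vq.cylinder_phantom(radius=6.0, length=60.0)


@pytest.fixture(scope="session")
def cylinder8():
    """Straight vertical cylinder, radius 8 mm, length 60 mm, 1 mm grid."""
    return vq.cylinder_phantom(radius=8.0, length=60.0)


@pytest.fixture(scope="session")
def bifurcation():
    """Aorto-iliac-style bifurcation phantom with default geometry."""
    return vq.bifurcation_phantom()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
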