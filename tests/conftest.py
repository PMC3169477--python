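import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from heartvol.phantom import HeartPhantom, make_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def canine():
    return make_phantom("canine", seed=1)


@pytest.fixture(scope="session")
def human():
    return make_phantom("human", seed=1)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Spherical LV cavity (r = 20 mm), untruncated: every closed form known."""
    return HeartPhantom((20.0, 20.0, 20.0), (26.0, 26.0, 26.0), 1.0,
                        (12.0, 12.0, 14.0))


@pytest.fixture(scope="session")
def revolution_phantom():
    """Axisymmetric truncated ellipsoid (solid of revolution when untilted)."""
    return make_phantom("canine", seed=3, axisymmetric=True)


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
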