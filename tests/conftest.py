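import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from srbeam3d import ScattererSet, make_probe, simulate_channels

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_probe():
    """8x8 matrix array: full physics, tiny channel count for fast tests."""
    return make_probe(n_lateral=8, n_elevation=8, aperture=(2.4, 2.55))


@pytest.fixture(scope="session")
def point_frame(small_probe):
    """Noiseless frame of a single unit scatterer at (0.2, -0.1, 12) mm."""
    scene = ScattererSet(np.array([[0.2, -0.1, 12.0]]), np.array([1.0]))
    return simulate_channels(small_probe, scene, duration=25.0), scene
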