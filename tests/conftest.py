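import numpy as np
import pytest

from socialgaze.geometry import ViewingGeometry, default_geometry


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def small_geometry():
    """A downscaled screen for fast map-level tests (same angular size)."""
    return ViewingGeometry(
        screen_width_cm=30.6,
        screen_height_cm=23.0,
        viewing_distance_cm=52.5,
        image_width_px=240,
        image_height_px=180,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
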