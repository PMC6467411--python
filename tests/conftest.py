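import numpy as np
import pytest

from activelight import ControllerParams, SceneConfig, make_scene
from activelight.plant import DiffuserPSF


@pytest.fixture
def params():
    return ControllerParams()


@pytest.fixture
def flat_scene():
    """Fully transparent, noiseless scene: plate covers the frame, no worms.

    The closed loop on this plant has the exact unit-normalized operating
    point: uniform action 445 renders a uniform background of 48.
    """
    cfg = SceneConfig(
        n_worms=0,
        media_mean=1.0,
        media_amplitude=0.0,
        wall_ring_fraction=0.0,
        plate_radius=1000.0,
        noise=False,
        seed=0,
    )
    return make_scene(cfg)


@pytest.fixture
def small_scene_config():
    """Coarse, fast scene with a plate, wall ring and worms (noiseless)."""
    return SceneConfig(
        image_shape=(128, 128),
        grid_shape=(28, 28),
        texel_pitch=4.0,
        grid_offset=(7.0, 7.0),
        plate_center=(64.0, 64.0),
        plate_radius=58.0,
        media_corr_px=18.0,
        worm_length_px=16.0,
        n_worms=3,
        noise=False,
        seed=11,
    )
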