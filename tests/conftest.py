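import numpy as np
import pytest

from irrimap.raster import GridSpec, ScalarMap
from irrimap.synth import SceneConfig, generate_scene


@pytest.fixture
def grid4():
    return GridSpec(4, 4, origin_x=0.0, origin_y=1000.0, pixel_size=250.0, crs_id="EPSG:32643")


@pytest.fixture
def slope_flat(grid4):
    return ScalarMap(grid4, np.zeros((4, 4), dtype=np.float32), units="percent")


@pytest.fixture(scope="session")
def default_scene():
    """The standard noisy study scene: 64x64, boost 0.2, noise sd 0.02."""
    return generate_scene(SceneConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_scene():
    return generate_scene(SceneConfig(seed=3, noise_sd=0.0))
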