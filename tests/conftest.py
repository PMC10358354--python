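import numpy as np
import pytest

from fieldsynth import (
    PlantStyle,
    ScaleRange,
    SoilStyle,
    gen_plant,
    gen_plant_cutout,
    gen_soil,
    gen_soil_pool,
    make_composite,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def plant_fixture():
    """One default blue-screen plant image with its ground-truth mask."""
    return gen_plant(PlantStyle(seed=7))


@pytest.fixture(scope="session")
def cutout_pool():
    species = ("canola", "oat", "soybean", "wheat")
    return [
        gen_plant_cutout(PlantStyle(seed=i, size_px=96), species=species[i % 4])
        for i in range(4)
    ]


@pytest.fixture(scope="session")
def soil_image():
    return gen_soil(SoilStyle(seed=11), 384, 384)


@pytest.fixture(scope="session")
def soil_pool():
    return gen_soil_pool(3, 384, 384, seed=11)


@pytest.fixture(scope="session")
def composite_tile(cutout_pool, soil_image):
    rng = np.random.default_rng(99)
    return make_composite(cutout_pool[0], soil_image, ScaleRange(), 128, rng, "soil-11")
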