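import numpy as np
import pytest

from mrimotion import SliceImage, generate_family, make_phantom, make_phantom_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_axial():
    return make_phantom(seed=7, plane="axial", size=256)


@pytest.fixture(scope="session")
def phantom_small():
    return make_phantom(seed=7, plane="axial", size=64)


@pytest.fixture(scope="session")
def phantom_set_small():
    return make_phantom_set(2, seed=3, size=64)


@pytest.fixture(scope="session")
def small_family():
    return generate_family(20, length_min=5, length_max=15, seed=42)


@pytest.fixture
def constant_image():
    return SliceImage(np.full((64, 64), 0.5), plane="axial", id="const")
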