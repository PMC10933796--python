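import numpy as np
import pytest

from histoslice.core import TensorImage
from histoslice.synthetic import PhantomSpec, make_phantom_volume, make_slab_photo


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_volume():
    """Small phantom volume shared by the cheaper 3-D tests."""
    return make_phantom_volume(PhantomSpec(shape=(64, 64, 64), seed=7))


@pytest.fixture(scope="session")
def slab_pair():
    """Slab photo plus its texture-free structural pattern."""
    return make_slab_photo(seed=3)


@pytest.fixture()
def textured_image():
    """Reproducible smooth-blob test image (80x80 at 0.2 mm/px)."""
    from scipy.ndimage import gaussian_filter

    g = np.random.default_rng(7)
    data = gaussian_filter(g.standard_normal((80, 80)), 2.5)
    data = (data - data.min()) / (data.max() - data.min())
    return TensorImage(data, resolution=(0.2, 0.2))
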