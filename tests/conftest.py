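import numpy as np
import pytest
from scipy import ndimage

from fibrekit import MultiChannelImage, PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def stripe_raster():
    """Vertical sinusoidal stripes on a 256x256 raster (fibre axis at 90 deg)."""
    x = np.linspace(0, 16 * np.pi, 256)
    return 0.5 + 0.5 * np.sin(np.tile(x, (256, 1)))


@pytest.fixture
def line_raster():
    """A single drawn diagonal line of ~283 px, softly blurred."""
    img = np.zeros((256, 256))
    for i in range(20, 220):
        img[i, i] = 1.0
    return ndimage.gaussian_filter(
        ndimage.binary_dilation(img > 0, iterations=1).astype(float), 1.0
    )


@pytest.fixture
def small_image(rng):
    """A tiny random-but-valid multi-channel field."""
    return MultiChannelImage(
        shg=rng.random((32, 32)),
        pl=rng.random((32, 32)),
        trans=rng.random((32, 32)),
        field_id="fixture",
    )


@pytest.fixture
def phantom():
    """Default phantom field plus ground truth, fixed seed."""
    return make_phantom(PhantomSpec(seed=7))
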