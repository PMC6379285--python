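import numpy as np
import pytest

from sitvolumetry import (
    NoduleSpec,
    PhantomSpec,
    SphericalROI,
    VolumetricImage,
    compose_phantom,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260)


@pytest.fixture
def random_image(rng):
    """Small random image on an anisotropic grid."""
    data = rng.uniform(0.0, 1000.0, size=(24, 20, 16))
    return VolumetricImage(data, spacing=(0.9, 1.1, 1.4))


@pytest.fixture
def binary_phantom():
    """Noise-free, blur-free, background-zero phantom: two intensity
    populations (0 and the nodule plateau), occupancy binarized by
    supersample=1 rasterization."""
    nod = NoduleSpec("n1", center=(14.0, 14.0, 14.0), volume_true=113.1, shape="sphere")
    spec = PhantomSpec(
        grid_shape=(29, 29, 29),
        spacing=(1.0, 1.0, 1.0),
        nodules=[nod],
        nodule_signal=100.0,
        background_mean=0.0,
        background_texture_sd=0.0,
        blur_fwhm=0.0,
        noise_sd=0.0,
        supersample=1,
        seed=11,
    )
    image, truth = compose_phantom(spec)
    roi = SphericalROI(nod.center, 8.0)
    return image, roi, nod


@pytest.fixture
def blurred_phantom():
    """Deterministic phantom with partial-volume blur but no noise."""
    nod = NoduleSpec("n1", center=(14.0, 14.0, 14.0), volume_true=200.0,
                     shape="hemisphere")
    spec = PhantomSpec(
        grid_shape=(29, 29, 29),
        spacing=(1.0, 1.0, 1.0),
        nodules=[nod],
        nodule_signal=100.0,
        background_mean=10.0,
        background_texture_sd=2.0,
        blur_fwhm=1.2,
        noise_sd=0.0,
        supersample=4,
        seed=7,
    )
    image, _ = compose_phantom(spec)
    roi = SphericalROI(nod.center, 9.0)
    return image, roi, nod
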