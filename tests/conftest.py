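import numpy as np
import pytest
from scipy import ndimage

from lavatrack.image_model import BinaryMask3D, ScalarVolume3D
from lavatrack.synthetic_data import PhantomSpec, generate_phantom_study


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def smooth_random_volume(rng, shape=(16, 14, 12), spacing=(2.0, 2.0, 2.0),
                         lo=-950.0, hi=-400.0, sigma=2.0):
    """A smooth random HU field, used where interpolation accuracy matters."""
    raw = rng.uniform(lo, hi, shape)
    smooth = ndimage.gaussian_filter(raw, sigma)
    return ScalarVolume3D(smooth, spacing)


@pytest.fixture
def smooth_volume(rng):
    return smooth_random_volume(rng)


def full_mask(vol) -> BinaryMask3D:
    return BinaryMask3D(np.ones(vol.shape, bool), vol.spacing, vol.origin)


def interior_mask(vol, margin=2) -> BinaryMask3D:
    m = np.zeros(vol.shape, bool)
    sl = tuple(slice(margin, n - margin) for n in vol.shape)
    m[sl] = True
    return BinaryMask3D(m, vol.spacing, vol.origin)


def small_phantom_spec(**kw) -> PhantomSpec:
    """A reduced 40^3 / 4 mm phantom covering the same physical field of view."""
    defaults = dict(dims=(40, 40, 40), spacing_mm=(4.0, 4.0, 4.0), seed=11)
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return generate_phantom_study(small_phantom_spec())


@pytest.fixture(scope="session")
def default_study():
    """The full-size noise-free phantom study (96^3 at 2 mm)."""
    return generate_phantom_study(PhantomSpec())
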