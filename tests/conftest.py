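import numpy as np
import pytest
from scipy import ndimage

from contourqa.volume import BinaryMask, ImageVolume, StructureSet
from contourqa.phantoms import PhantomSpec, make_phantom

ANISO_SPACING = (1.1875, 1.1875, 3.0)


def cube_mask(n: int, grid=(16, 16, 16), spacing=(1.0, 1.0, 1.0),
              offset=(3, 3, 3)) -> BinaryMask:
    data = np.zeros(grid, dtype=bool)
    ox, oy, oz = offset
    data[ox:ox + n, oy:oy + n, oz:oz + n] = True
    return BinaryMask(data, spacing)


def random_blob_pair(rng: np.random.Generator, shape=(12, 12, 8),
                     spacing=ANISO_SPACING):
    """Two correlated nonempty random masks on a small anisotropic grid."""
    while True:
        base = ndimage.gaussian_filter(rng.normal(size=shape), 1.5)
        noise = ndimage.gaussian_filter(rng.normal(size=shape), 1.5)
        a = base > np.percentile(base, 65)
        b = (base + 0.6 * noise) > np.percentile(base + 0.6 * noise, 65)
        if a.any() and b.any() and not a.all() and not b.all():
            return BinaryMask(a, spacing), BinaryMask(b, spacing)


@pytest.fixture(scope="session")
def clean_phantom():
    """Default 12-organ phantom without bias or noise."""
    spec = PhantomSpec(bias_amplitude=0.0, noise_sd=0.0, seed=11)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def biased_phantom():
    """Default 12-organ phantom with a 0.3-amplitude bias field, no noise."""
    spec = PhantomSpec(bias_amplitude=0.3, noise_sd=0.0, seed=11)
    return make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
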