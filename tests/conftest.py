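import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from massdetect import PhantomCase, generate_phantom


@pytest.fixture
def small_case() -> PhantomCase:
    """256-pixel phantom with two masses for fast unit tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_phantom(256, 256, 2, density=0.3, mass_contrast=0.6, seed=3)


@pytest.fixture
def flat_case() -> PhantomCase:
    """Hand-built case with a full-frame breast mask and no masses."""
    rng = np.random.default_rng(0)
    image = 0.2 + 0.05 * rng.random((256, 256))
    return PhantomCase(image=image, breast_mask=np.ones((256, 256), dtype=bool))


def tiny_texture(shape, seed):
    """Reproducible smooth test image in [0, 1]."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.random(shape), sigma=3)
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo)
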