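import numpy as np
import pytest

from microwear import HeightMap


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def random_surface(rng):
    """A generic random rough surface (smoothed noise, fully valid)."""
    from scipy import ndimage

    z = ndimage.gaussian_filter(rng.standard_normal((64, 64)), 2.0)
    return HeightMap(z, 0.5, 0.5)
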