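import numpy as np
import pytest

from mesomap.atlas import make_atlas
from mesomap.optics import default_optics
from mesomap.spectroscopy import HemoMovie


@pytest.fixture(scope="session")
def atlas64():
    return make_atlas(64, 64, pixel_size=0.156)


@pytest.fixture(scope="session")
def atlas128():
    return make_atlas(128, 128)


@pytest.fixture(scope="session")
def optics():
    return default_optics()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def movie_from_hbt(hbt, frame_rate=1.0, mask=None):
    """HemoMovie carrying a given HbT exactly (hbo = hbr = hbt/2)."""
    hbt = np.asarray(hbt, dtype=float)
    if mask is None:
        mask = np.ones(hbt.shape[1:], dtype=bool)
    half = 0.5 * hbt
    return HemoMovie(hbo=half, hbr=half, hbt=half + half,
                     frame_rate=frame_rate, mask=mask)
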