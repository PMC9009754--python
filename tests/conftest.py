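import numpy as np
import pytest

from thzshrink import Spectrum, la_filters


@pytest.fixture
def la8():
    return la_filters(8)


@pytest.fixture
def thz_axis():
    """Default analysis grid: 0.2-1.8 THz at 5 GHz spacing (321 samples)."""
    return 0.2 + 0.005 * np.arange(321)


def make_spectrum(values, axis=None, kind="reflectivity", band=None):
    if axis is None:
        axis = 0.2 + 0.005 * np.arange(len(values))
    if band is None:
        band = (float(axis[0]), float(axis[-1]))
    return Spectrum(np.asarray(axis, float), np.asarray(values, float), band, kind)
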