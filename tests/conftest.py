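import numpy as np
import pytest

from monorelief.raster_io import RegionMask


@pytest.fixture
def full_mask_8():
    return RegionMask(np.ones((8, 8), dtype=bool))


@pytest.fixture
def full_mask_16():
    return RegionMask(np.ones((16, 16), dtype=bool))


@pytest.fixture
def full_mask_32():
    return RegionMask(np.ones((32, 32), dtype=bool))


def pearson(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return float(np.corrcoef(a, b)[0, 1])
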