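import numpy as np
import pytest

from coastcr.habitat import (
    GridSpec,
    HabitatMask,
    INSHORE,
    ISLAND,
    STRATUM_CODES,
)


@pytest.fixture
def all_water_mask():
    """10 x 10 km single-stratum (Inshore) mask with 1 km cells."""
    water = np.ones((10, 10), dtype=bool)
    stratum = np.full((10, 10), STRATUM_CODES[INSHORE], dtype=np.int8)
    return HabitatMask((0.0, 0.0), 1.0, water, stratum)


@pytest.fixture
def two_stratum_mask():
    """16 x 8 km all-water mask with a 12-cell Island band on row 0."""
    water = np.ones((8, 16), dtype=bool)
    stratum = np.full((8, 16), STRATUM_CODES[INSHORE], dtype=np.int8)
    stratum[0, 2:14] = STRATUM_CODES[ISLAND]
    return HabitatMask((0.0, 0.0), 1.0, water, stratum)


@pytest.fixture
def grid_10():
    return GridSpec((0.0, 0.0), 10, 10, 1.0)


def make_two_stratum_mask():
    water = np.ones((8, 16), dtype=bool)
    stratum = np.full((8, 16), STRATUM_CODES[INSHORE], dtype=np.int8)
    stratum[0, 2:14] = STRATUM_CODES[ISLAND]
    return HabitatMask((0.0, 0.0), 1.0, water, stratum)
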