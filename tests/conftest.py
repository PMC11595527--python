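import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from corridorscape.raster import GridContract, Raster


@pytest.fixture
def grid300():
    """A 20x20 grid of 300 m cells (the study resolution)."""
    return GridContract(20, 20, 300.0)


def make_raster(data, cell_size=300.0):
    data = np.asarray(data)
    h, w = data.shape
    return Raster(data, GridContract(w, h, cell_size))


@pytest.fixture
def raster_factory():
    return make_raster
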