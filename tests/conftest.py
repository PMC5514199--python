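import numpy as np
import pytest

from landfrag import MF, NF, SF, CategoricalRaster


@pytest.fixture
def checkerboard():
    """8x8 two-class checkerboard: every rook neighbour is the other class."""
    parity = np.indices((8, 8)).sum(axis=0) % 2
    return CategoricalRaster(np.where(parity == 0, MF, NF).astype(np.int16), year=2000)


@pytest.fixture
def square_in_matrix():
    """10x10 non-forest landscape with a centred 2x2 mature-forest patch."""
    grid = np.full((10, 10), NF, dtype=np.int16)
    grid[4:6, 4:6] = MF
    return CategoricalRaster(grid, year=2000)


@pytest.fixture
def clearing_series():
    """3-year 6x6 series: solid forest, then a 2x2 clearing, then regrowth."""
    base = np.full((6, 6), MF, dtype=np.int16)
    y1 = base.copy()
    y2 = base.copy()
    y2[2:4, 2:4] = NF
    y3 = y2.copy()
    y3[2, 2] = SF
    return [CategoricalRaster(g, year=y) for g, y in ((y1, 2000), (y2, 2001), (y3, 2002))]


def random_raster(rng, shape, codes=(MF, NF, SF), nodata_frac=0.0):
    grid = rng.choice(codes, size=shape).astype(np.int16)
    if nodata_frac:
        grid[rng.random(shape) < nodata_frac] = 0
    return CategoricalRaster(grid)
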