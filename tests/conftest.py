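import numpy as np
import pytest
from shapely.geometry import box

from magpie.grid import Grid, Zone, ZoneSet


@pytest.fixture
def simple_grid():
    """4x4 grid of 100 m cells with distinct values, origin at (0, 400)."""
    return Grid(np.arange(16, dtype=float).reshape(4, 4), 0.0, 400.0, 100.0, crs="t")


@pytest.fixture
def grid_factory():
    def make(values, cell_size_m=100.0, crs="t", nodata=-9999.0):
        values = np.asarray(values, dtype=float)
        return Grid(values, 0.0, values.shape[0] * cell_size_m, cell_size_m, crs=crs, nodata=nodata)

    return make


@pytest.fixture
def zone_factory():
    """Build a ZoneSet of rectangular zones: (zone_id, (xmin,ymin,xmax,ymax), count)."""

    def make(rects, year=2011, crs="t"):
        zones = [
            Zone(zid, box(*bounds), {year: count}) for zid, bounds, count in rects
        ]
        return ZoneSet(zones, crs=crs)

    return make
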