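import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import box

from occtool.geo_core import GeoGrid, LandCoverMap, PolygonSet

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def unit_grid():
    """10x10 grid of 0.1-degree cells over [0,1] x [0,1]."""
    return GeoGrid.from_extent(0.0, 0.0, 1.0, 1.0, n_rows=10, n_cols=10)


@pytest.fixture
def square_boundary():
    return PolygonSet(polygons=[box(0.0, 0.0, 1.0, 1.0)], names=["study_area"])


@pytest.fixture
def forest_map(unit_grid):
    """Uniform evergreen-forest map on the unit grid."""
    codes = np.full(unit_grid.shape, 50)
    return LandCoverMap(
        grid=unit_grid, codes=codes, valid=np.ones(unit_grid.shape, bool), year_label="t1"
    )


def random_landcover(grid, classes, rng):
    codes = rng.choice(classes, size=grid.shape)
    return LandCoverMap(grid=grid, codes=codes, valid=np.ones(grid.shape, bool))
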