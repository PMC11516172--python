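import numpy as np
import pytest

from pyroscape.grid_io import OccurrenceSet, RasterGrid, RasterStack

CRS = "EPSG:32638"
ORIGIN = (500_000.0, 3_900_000.0)


def make_grid(values, cell_size=1000.0, origin=ORIGIN, legend=None, mask=None):
    values = np.asarray(values)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return RasterGrid(values, mask, cell_size, origin, CRS, legend)


def make_stack(named_arrays, cell_size=1000.0):
    names = list(named_arrays)
    layers = [make_grid(named_arrays[n], cell_size=cell_size) for n in names]
    return RasterStack(layers, names)


def points_at_cells(grid, rows, cols, season="spring", label="presence"):
    x, y = grid.cell_center(np.asarray(rows), np.asarray(cols))
    return OccurrenceSet.from_records(
        [(float(xi), float(yi), season, label, "test") for xi, yi in zip(x, y)])


@pytest.fixture
def grid_10x10():
    rng = np.random.default_rng(42)
    return make_grid(rng.uniform(0, 1, (10, 10)))


@pytest.fixture
def small_landscape():
    """A 64x64 synthetic landscape shared by slower model-level tests."""
    from pyroscape.synthetic_landscape import LandscapeSpec, make_landscape

    spec = LandscapeSpec(shape=(64, 64), seed=7)
    return make_landscape(spec)
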