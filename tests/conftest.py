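import numpy as np
import pytest

from sdmeval.rasters_io import CategoricalMap, EnvStack, GridRaster, OccurrenceSet


@pytest.fixture
def small_grid():
    """3x3 grid, cell size 1, lower-left at (0, 0)."""
    return GridRaster(values=np.arange(9, dtype=float).reshape(3, 3),
                      x_origin=0.0, y_origin=3.0, cell_size=1.0)


@pytest.fixture
def binary_map_factory():
    def make(values, cell_size=1.0, nodata_code=-1):
        values = np.asarray(values)
        return CategoricalMap(values=values, x_origin=0.0,
                              y_origin=values.shape[0] * cell_size,
                              cell_size=cell_size, nodata_code=nodata_code)
    return make


@pytest.fixture
def random_binary_maps(binary_map_factory):
    """Seeded generator of aligned random binary map pairs."""
    def make(n_pairs, shape=(8, 8), seed=0):
        rng = np.random.default_rng(seed)
        for _ in range(n_pairs):
            a = binary_map_factory(rng.integers(0, 2, size=shape))
            b = binary_map_factory(rng.integers(0, 2, size=shape))
            yield a, b
    return make


@pytest.fixture
def stack_factory():
    def make(arrays, names=None, cell_size=1.0):
        arrays = [np.asarray(a, dtype=float) for a in arrays]
        names = names or [f"env{i + 1:02d}" for i in range(len(arrays))]
        y0 = arrays[0].shape[0] * cell_size
        return EnvStack({
            n: GridRaster(values=a, x_origin=0.0, y_origin=y0, cell_size=cell_size)
            for n, a in zip(names, arrays)
        })
    return make


@pytest.fixture
def points_factory():
    def make(x, y, label="presence"):
        return OccurrenceSet.from_arrays(x, y, label)
    return make
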