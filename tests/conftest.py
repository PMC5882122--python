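import numpy as np
import pytest

from landintegrity import GridSpec, Raster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(n_rows, n_cols, pixel_size=90.0, x0=0.0, y0=None):
    if y0 is None:
        y0 = n_rows * pixel_size
    return GridSpec(x0, y0, pixel_size, n_rows, n_cols, "test-m")


def make_raster(values, pixel_size=90.0, nodata=-9999.0):
    values = np.asarray(values, dtype=np.float64)
    return Raster(make_grid(*values.shape, pixel_size), values, nodata)


@pytest.fixture
def grid_factory():
    return make_grid


@pytest.fixture
def raster_factory():
    return make_raster
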