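import warnings

import numpy as np
import pytest

from piccsct.grid import ImageGrid, ProjectionGeometry
from piccsct.projector import Projector

# deep wavelet levels on small test grids trip a cosmetic pywt warning
warnings.filterwarnings("ignore", message="Level value .* is too high")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_grid():
    return ImageGrid(16, 16, 1.0)


@pytest.fixture(scope="session")
def small_geometry(small_grid):
    return ProjectionGeometry.for_grid(small_grid, np.arange(0, 360, 30.0))


@pytest.fixture(scope="session")
def small_projector(small_grid, small_geometry):
    return Projector(small_grid, small_geometry)


def dense_matrix(apply_fn, n_in, out_size=None):
    """Materialise a linear operator column by column (independent oracle)."""
    cols = []
    for j in range(n_in):
        e = np.zeros(n_in)
        e[j] = 1.0
        cols.append(np.asarray(apply_fn(e)).ravel())
    mat = np.column_stack(cols)
    if out_size is not None:
        assert mat.shape[0] == out_size
    return mat


@pytest.fixture(scope="session")
def dense_forward(small_grid, small_projector):
    """Dense F assembled by forward-projecting unit-pixel images."""
    shape = small_grid.shape

    def apply(vec):
        return small_projector.forward(vec.reshape(shape))

    return dense_matrix(apply, small_grid.n_pixels)
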