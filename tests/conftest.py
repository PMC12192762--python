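import numpy as np
import pytest

from maxsdm.grid_io import EnvGrid
from maxsdm.preprocess import extract_samples
from maxsdm.synthetic_data import (
    LandscapeSpec,
    sample_presences,
    simulate_landscape,
)


@pytest.fixture(scope="session")
def landscape():
    """Default 50x60 synthetic landscape (truth driven by bio12/bio6)."""
    spec = LandscapeSpec(seed=1)
    stack, truth = simulate_landscape(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def samples(landscape):
    _, stack, truth = landscape
    occ = sample_presences(truth, stack, n=600, seed=2)
    return extract_samples(stack, occ, n_background=1500, seed=3)


@pytest.fixture(scope="session")
def independent_landscape():
    """Landscape with uncorrelated layers, for coefficient recovery."""
    spec = LandscapeSpec(seed=7, cross_correlation=np.eye(8))
    stack, truth = simulate_landscape(spec)
    return spec, stack, truth


def make_grid(values, nodata=-9999.0, cellsize=1.0, xll=0.0, yll=0.0):
    values = np.asarray(values, dtype=float)
    return EnvGrid(
        ncols=values.shape[1],
        nrows=values.shape[0],
        xllcorner=xll,
        yllcorner=yll,
        cellsize=cellsize,
        nodata_value=nodata,
        values=values,
    )


@pytest.fixture
def grid_factory():
    return make_grid
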