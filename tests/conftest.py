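"""Shared fixtures: a small synthetic world carried through the pipeline."""

import numpy as np
import pytest

from ridge2reef.coral import fit_condition_model
from ridge2reef.grid import Grid
from ridge2reef.hydro import storm_sediment_loads
from ridge2reef.plume import tss_field
from ridge2reef.synth import generate_landscape, generate_surveys


@pytest.fixture(scope="session")
def world():
    """Default 64x64 island world (seed 1) with the hydro/plume chain run."""
    bundle = generate_landscape(seed=1)
    loads, grids = storm_sediment_loads(
        bundle.dem, bundle.storm_precip, bundle.curve_number, bundle.k_factor, bundle.c_factor
    )
    field = tss_field(loads, bundle.sea_mask)
    return {"bundle": bundle, "loads": loads, "grids": grids, "field": field}


@pytest.fixture(scope="session")
def coral_mask(world):
    coral = world["bundle"].feature_grids["coral"]
    return coral.like(np.asarray(coral.values) > 0)


@pytest.fixture(scope="session")
def surveys(world, coral_mask):
    return generate_surveys(
        world["field"].log_tss, coral_mask, world["bundle"].truth, seed=1
    )


@pytest.fixture(scope="session")
def condition_model(surveys):
    return fit_condition_model(surveys)


def make_island_dem(elevations, cell_size_m=100.0):
    """Embed a land elevation block inside a one-cell sea ring."""
    arr = np.asarray(elevations, dtype=float)
    nrows, ncols = arr.shape
    vals = np.zeros((nrows + 2, ncols + 2))
    vals[1:-1, 1:-1] = arr
    mask = np.ones_like(vals, dtype=bool)
    mask[1:-1, 1:-1] = False
    return Grid(vals, cell_size_m, nodata_mask=mask)
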