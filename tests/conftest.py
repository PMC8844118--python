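import numpy as np
import pytest

from climatch.grids import ClimateGrid, ClimateStack, GridSpec
from climatch.presets import SPECIES_PRESETS, default_generator_config
from climatch.synthetic_climate import generate_climate_pair
from climatch.virtual_species import (
    occurrence_probability,
    realize_presence_absence,
    suitability_from_responses,
)


def make_grid(values, cell_size=1.0, origin_y=None, mask=None, name="var"):
    """Helper: grid from a 2-D array, origin chosen so y > 0 inside."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=0.0,
        origin_y=origin_y if origin_y is not None else n_rows * cell_size,
        cell_size=cell_size,
        nodata_mask=mask,
    )
    return ClimateGrid(spec, values, name)


def make_stack(arrays: dict, cell_size=1.0, **tags) -> ClimateStack:
    grids = {name: make_grid(vals, cell_size=cell_size, name=name) for name, vals in arrays.items()}
    return ClimateStack(grids, **tags)


@pytest.fixture(scope="session")
def small_pair():
    """40x40 paired climate versions under the default study conditions."""
    cfg = default_generator_config(seed=7, n_rows=40, n_cols=40, scenarios=(), gcms=())
    return generate_climate_pair(cfg)


@pytest.fixture(scope="session")
def alpine_maps(small_pair):
    """Suitability, occurrence probability and presence-absence for the
    cold-adapted response-curve species on the reference stack."""
    preset = SPECIES_PRESETS["alpine"]
    hs = suitability_from_responses(small_pair.current_a, preset.responses)
    prob = occurrence_probability(hs, preset.conversion)
    pa = realize_presence_absence(prob, seed=11)
    return hs, prob, pa
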