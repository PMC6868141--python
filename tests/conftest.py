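import numpy as np
import pytest

import habishift as hs


@pytest.fixture(scope="session")
def grid40():
    return hs.GridSpec(40, 40, 50.0)


@pytest.fixture(scope="session")
def landscape40(grid40):
    """One-region landscape used for SDM fixtures."""
    return hs.generate_landscape(
        grid40, hs.LandscapeConfig(sea_fraction=0.2, n_regions=1), seed=42
    )


@pytest.fixture(scope="session")
def landscape_two_regions():
    grid = hs.GridSpec(30, 30, 50.0)
    return hs.generate_landscape(
        grid, hs.LandscapeConfig(sea_fraction=0.3, n_regions=2), seed=7
    )


@pytest.fixture(scope="session")
def community(landscape40):
    """Five synthetic species with unbiased sampling on the shared landscape."""
    cfg = hs.SpeciesConfig(n_records=250, bias_strength=0.0)
    return hs.generate_species(landscape40, 5, cfg, seed=3)


def predictor_matrix_at(landscape, cells, predictor_names):
    """Raw predictor values (n_cells, p) at (row, col) cells."""
    names, stack = hs.predictor_stack(landscape)
    flat = stack.reshape(len(names), -1)
    idx = [names.index(p) for p in predictor_names]
    lin = cells[:, 0] * landscape.grid.n_cols + cells[:, 1]
    return flat[idx][:, lin].T
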