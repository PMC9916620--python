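import numpy as np
import pytest

from corridorscape.pipeline import RunConfig
from corridorscape.resistance import build_resistance_table
from corridorscape.synthetic import (
    LandscapeConfig,
    PesticideConfig,
    generate_landscape,
    generate_pesticide_tables,
)
from corridorscape.toxload import build_toxic_load_table


def mini_landscape_config() -> LandscapeConfig:
    """A small, fast landscape retaining all structural features."""
    return LandscapeConfig(
        nrows=80,
        ncols=120,
        outer_ring_width=8,
        parcel_side_range=(10, 14),
        n_parcels=60,
    )


def mini_run_config(seed: int = 0, iterations: int = 2) -> RunConfig:
    return RunConfig(
        point_spacing_m=600.0,
        max_pair_distance_m=5_000.0,
        jitter_radius_m=300.0,
        n_iterations=iterations,
        master_seed=seed,
    )


@pytest.fixture(scope="session")
def mini_landscape():
    return generate_landscape(mini_landscape_config(), seed=7)


@pytest.fixture(scope="session")
def mini_tables(mini_landscape):
    grid, _ = mini_landscape
    return generate_pesticide_tables(grid, PesticideConfig(), seed=7)


@pytest.fixture(scope="session")
def mini_resistance_table(mini_tables):
    records, ld50s, acreage = mini_tables
    return build_resistance_table(build_toxic_load_table(records, ld50s, acreage).scenario)


@pytest.fixture(scope="session")
def default_landscape():
    """The full default study landscape (session-scoped: generated once)."""
    return generate_landscape(LandscapeConfig(), seed=1)


def uniform_grid(nrows=10, ncols=10, value=1.0):
    return np.full((nrows, ncols), float(value))
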