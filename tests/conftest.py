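import numpy as np
import pandas as pd
import pytest

from phenostack.geodata_io import EnvStack, GridSpec, OccurrenceTable
from phenostack.synthetic import SyntheticConfig, simulate_environment, simulate_populations


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Small synthetic landscape used across module tests."""
    return SyntheticConfig(n_rows=60, n_cols=40, seed=11)


@pytest.fixture(scope="session")
def small_env(small_cfg):
    return simulate_environment(small_cfg)


@pytest.fixture(scope="session")
def small_occ(small_cfg, small_env):
    return simulate_populations(small_env, small_cfg)


@pytest.fixture
def grid10() -> GridSpec:
    return GridSpec(n_rows=10, n_cols=10, origin_lon=-110.0, origin_lat=45.0, cell_size=0.5)


def make_env(grid: GridSpec, seed: int = 0, n_layers: int = 2) -> EnvStack:
    """Random little stack for unit tests (layers l0, l1, ...)."""
    rng = np.random.default_rng(seed)
    layers = {f"l{i}": rng.normal(size=grid.shape) for i in range(n_layers)}
    return EnvStack(grid, layers)


def make_occurrences(days, grid: GridSpec | None = None, populations=None) -> OccurrenceTable:
    """Occurrence table with given leaf-out days, spread over distinct cells."""
    n = len(days)
    grid = grid or GridSpec(n_rows=max(1, n), n_cols=1, origin_lon=0.0, origin_lat=float(max(1, n)), cell_size=1.0)
    pops = populations or ["central"] * n
    return OccurrenceTable(
        pd.DataFrame(
            {
                "genotype_id": [f"g{i:03d}" for i in range(n)],
                "lon": [grid.origin_lon + 0.5 * grid.cell_size] * n,
                "lat": [grid.origin_lat - (i + 0.5) * grid.cell_size for i in range(n)],
                "population": pops,
                "leafout_day": list(days),
            }
        )
    )
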