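import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import grazemap as g

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def country_bundle():
    """Mid-sized synthetic country shared by the slower integration tests."""
    return g.generate(g.SynthConfig(seed=3, n_rows=160, n_cols=160, n_settlements=40))


@pytest.fixture(scope="session")
def country_pipeline(country_bundle):
    scenario_configs = [
        g.ScenarioConfig(settlement_radius_km=r, offtake_mode=m)
        for r in (10.0, 20.0)
        for m in ("BAU", "max")
    ]
    return g.run_pipeline(country_bundle, scenario_configs=scenario_configs)


def uniform_supply(n_rows=5, n_cols=5, pixel_mj=10.0, cell_size=500.0):
    """Supply raster with every pixel holding the same total energy (MJ)."""
    grid = g.Grid(n_rows, n_cols, cell_size)
    energy = np.full((n_rows, n_cols), pixel_mj / grid.cell_area)
    usable = np.full((n_rows, n_cols), int(g.UsableClass.GRASSLAND), dtype=np.int8)
    return g.SupplyRaster(grid, energy, usable)


def one_settlement(grid, district_id=0, population=1000, sid=1):
    """Settlement frame with a single settlement at the grid center."""
    return pd.DataFrame(
        {
            "settlement_id": [sid],
            "x": [grid.x_origin + grid.n_cols * grid.cell_size / 2],
            "y": [grid.y_origin - grid.n_rows * grid.cell_size / 2],
            "population": [population],
            "district_id": [district_id],
        }
    )


def demand_frame(entries):
    """[(sid, species, farm_type, mj), ...] → settlement demand table."""
    return pd.DataFrame(
        entries, columns=["settlement_id", "species", "farm_type", "grazing_demand"]
    )
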