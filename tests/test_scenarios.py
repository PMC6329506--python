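"""Pasture productivity table and production-expansion scenarios."""

import numpy as np
import pandas as pd
import pytest

import grazemap as g
from grazemap.errors import ValidationError
from grazemap.scenarios import landscape_partition


def prod_frame(species="cattle", farm_type="AE", meat_t=0.0, milk_t=0.0):
    return pd.DataFrame(
        [{"species": species, "farm_type": farm_type, "meat_t": meat_t, "milk_t": milk_t}]
    )


def area_frame(km2, species="cattle", farm_type="AE"):
    return pd.DataFrame([{"species": species, "farm_type": farm_type, "area_km2": km2}])


class TestProductivityTable:
    def test_meat_yield_per_thousand_km2(self):
        """28.44 kt of beef on 0.29597 million km² → 96.09 t per thousand km²."""
        out = g.productivity_table(
            prod_frame(meat_t=28_440.0), area_frame(295_970.0), area_basis_km2=1000.0
        )
        assert out["meat_yield"].iloc[0] == pytest.approx(96.09, abs=0.01)

    def test_zero_production_zero_yield(self):
        out = g.productivity_table(prod_frame(), area_frame(100.0))
        assert out["meat_yield"].iloc[0] == 0.0
        assert out["milk_yield"].iloc[0] == 0.0

    def test_milk_denominator_scaled_by_dairy_fraction(self):
        """100 kt of milk on 1.0 M km² with dairy fraction 0.5 divides by 0.5 M km²."""
        out = g.productivity_table(
            prod_frame(milk_t=100_000.0), area_frame(1_000_000.0), {"AE": 0.5}
        )
        assert out["milk_yield"].iloc[0] == pytest.approx(100_000.0 / 500_000.0)

    def test_zero_area_with_production_raises(self):
        with pytest.raises(ValidationError):
            g.productivity_table(prod_frame(meat_t=5.0), area_frame(0.0))


def test_percent_increase_arithmetic():
    """130 kt additional on a 417 kt baseline is a 31% increase."""
    assert round(100 * 130.0 / 417.0) == 31


class TestExpansionFixture:
    """4 unclaimed usable pixels of 10 MJ within 10 km: 8 MJ additional at a
    0.20 district rate, 12 MJ at the 0.30 maximum sustainable rate."""

    def build(self):
        grid = g.Grid(2, 2, 500.0)
        pixel_mj = 10.0
        energy = np.full((2, 2), pixel_mj / grid.cell_area)
        usable = np.full((2, 2), int(g.UsableClass.GRASSLAND), dtype=np.int8)
        supply = g.SupplyRaster(grid, energy, usable)
        setts = pd.DataFrame(
            {
                "settlement_id": [1],
                "x": [500.0],
                "y": [-500.0],
                "population": [100],
                "district_id": [0],
            }
        )
        district_raster = g.DistrictRaster(grid, np.zeros((2, 2), dtype=int))
        # empty calibrated run: zero demand, nothing claimed
        demands = pd.DataFrame(
            [{"settlement_id": 1, "species": "cattle", "farm_type": "AE", "grazing_demand": 0.0}]
        )
        result = g.run_allocation(supply, setts, demands, 0.20)
        assignment = g.OfftakeAssignment(
            table=pd.DataFrame(
                [
                    {
                        "district_id": 0,
                        "rate": 0.20,
                        "provenance": "reference",
                        "median_distance_km": 1.0,
                    }
                ]
            ),
            config=g.CalibrationConfig(),
        )
        productivity = pd.DataFrame(
            [
                {
                    "species": "cattle",
                    "farm_type": "AE",
                    "area_km2": 1.0,
                    "meat_t": 0.0,
                    "meat_yield": 2.0,
                    "milk_t": 0.0,
                    "milk_yield": 10.0,
                }
            ]
        )
        per_head = pd.DataFrame(
            [
                {
                    "species": "cattle",
                    "farm_type": "AE",
                    "grazing_mj_per_head": 2.0,
                    "meat_kg_per_head": 1.0,
                    "milk_kg_per_head": 5.0,
                }
            ]
        )
        return supply, setts, district_raster, result, assignment, productivity, per_head, demands

    def expand(self, mode):
        supply, setts, draster, result, assignment, productivity, per_head, demands = self.build()
        cfg = g.ScenarioConfig(settlement_radius_km=10.0, offtake_mode=mode)
        return g.expansion_potential(
            result,
            supply,
            setts,
            assignment,
            draster,
            cfg,
            productivity,
            per_head,
            baseline_beef_t=100.0,
            baseline_milk_t=200.0,
            demand_table=demands,
        )

    def test_bau_energy_at_district_rate(self):
        out = self.expand("BAU")
        assert out.additional_energy_mj == pytest.approx(8.0)
        assert out.additional_area_km2 == pytest.approx(4 * 0.25)

    def test_max_mode_energy_at_max_rate(self):
        out = self.expand("max")
        assert out.additional_energy_mj == pytest.approx(12.0)

    def test_both_conversion_paths_reported(self):
        out = self.expand("BAU")
        # area path: 1 km² × 2 t/km²; per-head path: 8 MJ / 2 MJ per head × 1 kg
        assert out.additional_beef_t["area_yield"] == pytest.approx(2.0)
        assert out.additional_beef_t["energy_per_head"] == pytest.approx(4.0 / 1000.0)
        assert out.pct_increase_beef["area_yield"] == pytest.approx(2.0)


class TestScenarioInvariants:
    def test_max_mode_dominates_bau(self, country_pipeline):
        """With all district rates ≤ 0.30, the max-rate scenario frees at least
        as much energy as business-as-usual at the same radius."""
        by_key = {(s.radius_km, s.mode): s for s in country_pipeline.scenarios}
        rates = country_pipeline.assignment.table["rate"]
        if (rates.dropna() <= 0.30).all():
            for radius in (10.0, 20.0):
                assert (
                    by_key[(radius, "max")].additional_energy_mj
                    >= by_key[(radius, "BAU")].additional_energy_mj - 1e-6
                )

    def test_area_monotone_in_radius(self, country_pipeline):
        by_key = {(s.radius_km, s.mode): s for s in country_pipeline.scenarios}
        for mode in ("BAU", "max"):
            assert (
                by_key[(20.0, mode)].additional_area_km2
                >= by_key[(10.0, mode)].additional_area_km2
            )

    def test_landscape_partition_complete(self, country_pipeline, country_bundle):
        parts = landscape_partition(
            country_pipeline.calibrated,
            country_pipeline.supply,
            country_bundle.settlements,
            10.0,
        )
        total = sum(p.sum() for p in parts.values())
        assert total == country_pipeline.supply.grid.n_pixels
        stacked = np.stack(list(parts.values()))
        assert (stacked.sum(axis=0) == 1).all()  # each pixel in exactly one part
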