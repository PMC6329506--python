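"""Demand side: herd-age disaggregation, energy demand, fodder, settlement split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import grazemap as g
from grazemap.errors import ConfigurationError, ValidationError

DISTRICTS = pd.DataFrame({"district_id": [1, 2], "province_id": [0, 0]})


def census_frame(groups):
    return pd.DataFrame(
        [
            {"province_id": 0, "species": "cattle", "age_group": name, "head": head}
            for name, head in groups.items()
        ]
    )


def counts_frame(head, district=1):
    return pd.DataFrame(
        [{"district_id": district, "species": "cattle", "farm_type": "HH", "head": head}]
    )


class TestHerdDisaggregation:
    def test_census_share_applied(self):
        """1000 district head × (400 / 2000) census share → 200 in the group."""
        ages = g.disaggregate_herd_ages(
            counts_frame(1000), census_frame({"A": 400, "B": 1600}), DISTRICTS
        )
        got = ages.set_index("age_group")["head"]
        assert got["A"] == pytest.approx(200.0)
        assert got["B"] == pytest.approx(800.0)

    def test_conservation(self):
        ages = g.disaggregate_herd_ages(
            counts_frame(100), census_frame({"A": 20, "B": 30, "C": 50}), DISTRICTS
        )
        np.testing.assert_allclose(ages["head"], [20, 30, 50])
        assert ages["head"].sum() == pytest.approx(100.0, rel=1e-12)

    def test_zero_district_count(self):
        ages = g.disaggregate_herd_ages(
            counts_frame(0), census_frame({"A": 400, "B": 1600}), DISTRICTS
        )
        assert (ages["head"] == 0).all()

    def test_zero_census_with_nonzero_count_names_district(self):
        with pytest.raises(ValidationError, match="1"):
            g.disaggregate_herd_ages(counts_frame(50), census_frame({"A": 0, "B": 0}), DISTRICTS)


class TestEnergyDemand:
    NUTRITIVE = pd.DataFrame(
        [{"species": "cattle", "age_group": "A", "farm_type": "HH", "mj_per_head": 20_000.0}]
    )

    def ages(self, head):
        return pd.DataFrame(
            [
                {
                    "district_id": 1,
                    "species": "cattle",
                    "farm_type": "HH",
                    "age_group": "A",
                    "head": head,
                }
            ]
        )

    def test_head_times_requirement(self):
        out = g.herd_energy_demand(self.ages(5), self.NUTRITIVE)
        assert out["total_demand"].iloc[0] == pytest.approx(100_000.0)

    def test_zero_head_zero_demand(self):
        out = g.herd_energy_demand(self.ages(0), self.NUTRITIVE)
        assert out["total_demand"].iloc[0] == 0.0

    def test_linearity(self):
        one = g.herd_energy_demand(self.ages(7), self.NUTRITIVE)["total_demand"].iloc[0]
        two = g.herd_energy_demand(self.ages(14), self.NUTRITIVE)["total_demand"].iloc[0]
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_missing_table_entry_raises(self):
        bad = self.ages(5).assign(age_group="unknown")
        with pytest.raises(ConfigurationError):
            g.herd_energy_demand(bad, self.NUTRITIVE)


class TestFodderAllocation:
    SHARES = pd.DataFrame(
        [
            {"province_id": 0, "species": "cattle", "share": 0.60},
            {"province_id": 0, "species": "sheep_goats", "share": 0.20},
            {"province_id": 0, "species": "pigs_poultry", "share": 0.20},
        ]
    )
    CONVERSION = pd.DataFrame([{"fodder_type": "hay", "mj_per_kg": 6.0}])

    def production(self, kg):
        return pd.DataFrame(
            [{"district_id": 1, "farm_type": "HH", "fodder_type": "hay", "kg": kg}]
        )

    def test_share_times_conversion(self):
        """100,000 kg hay × 6 MJ/kg × 0.60 cattle share → 360,000 MJ."""
        out = g.allocate_fodder(self.production(100_000), self.SHARES, self.CONVERSION, DISTRICTS)
        cattle = out[out["species"] == "cattle"]["fodder_energy"].iloc[0]
        assert cattle == pytest.approx(360_000.0)

    def test_allocated_total_bounded_by_production_energy(self):
        out = g.allocate_fodder(self.production(100_000), self.SHARES, self.CONVERSION, DISTRICTS)
        assert out["fodder_energy"].sum() <= 100_000 * 6.0 + 1e-9

    def test_zero_shares_zero_energy(self):
        shares = self.SHARES.assign(share=0.0)
        out = g.allocate_fodder(self.production(100_000), shares, self.CONVERSION, DISTRICTS)
        assert (out["fodder_energy"] == 0).all()

    def test_unknown_fodder_type_raises(self):
        bad = self.production(10).assign(fodder_type="silage")
        with pytest.raises(ConfigurationError):
            g.allocate_fodder(bad, self.SHARES, self.CONVERSION, DISTRICTS)


def ledger_frame(total_pj, fodder_pj):
    total = pd.DataFrame(
        [{"district_id": 1, "species": "cattle", "farm_type": "HH", "total_demand": total_pj * 1e9}]
    )
    fodder = pd.DataFrame(
        [{"district_id": 1, "species": "cattle", "farm_type": "HH", "fodder_energy": fodder_pj * 1e9}]
    )
    return g.build_ledger(total, fodder)


class TestLedger:
    def test_national_balance(self):
        """368 PJ demand with 82 PJ fodder leaves 286 PJ of grazing demand (gap 0.78)."""
        nat = ledger_frame(368.0, 82.0).national()
        assert nat["grazing_demand_mj"] == pytest.approx(286e9)
        assert round(nat["grazing_gap"], 2) == 0.78

    def test_surplus_fodder_clamped(self):
        nat = ledger_frame(10.0, 15.0).national()
        assert nat["grazing_demand_mj"] == 0.0
        assert nat["grazing_gap"] == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ledger_frame(-1.0, 0.0)

    @given(fodder=st.lists(st.floats(min_value=0, max_value=400), min_size=2, max_size=6))
    def test_gap_bounded_and_monotone_in_fodder(self, fodder):
        gaps = [ledger_frame(368.0, f).national()["grazing_gap"] for f in sorted(fodder)]
        assert all(0 <= gp <= 1 for gp in gaps)
        assert all(a >= b - 1e-12 for a, b in zip(gaps, gaps[1:]))


class TestOwnerFraction:
    @pytest.mark.parametrize(
        "pop,frac",
        [
            (0, 0.95),
            (500, 0.95),
            (1_000, 0.95),
            (5_000, 0.80),
            (7_500, 0.55),  # midpoint of the (5000, 0.80)–(10000, 0.30) segment
            (10_000, 0.30),
            (50_000, 0.10),
            (1_000_000, 0.005),
            (5_000_000, 0.005),
        ],
    )
    def test_knots_and_interpolation(self, pop, frac):
        assert g.owner_fraction(pop) == pytest.approx(frac)

    def test_negative_population_rejected(self):
        with pytest.raises(ValidationError):
            g.owner_fraction(-1)


class TestSettlementSplit:
    def settlements(self, pops, district=1):
        return pd.DataFrame(
            {
                "settlement_id": range(1, len(pops) + 1),
                "x": np.zeros(len(pops)),
                "y": np.zeros(len(pops)),
                "population": pops,
                "district_id": district,
            }
        )

    def test_owner_damped_weights(self):
        """Populations (1000, 10000) weigh 950 and 3000, splitting 950/3950 vs 3000/3950."""
        ledger = ledger_frame(1.0, 0.0)
        out = g.settlement_demand(ledger, self.settlements([1_000, 10_000]))
        got = out.settlement_table.set_index("settlement_id")["grazing_demand"]
        assert got[1] == pytest.approx(1e9 * 950 / 3950)
        assert got[2] == pytest.approx(1e9 * 3000 / 3950)

    def test_single_settlement_gets_everything(self):
        ledger = ledger_frame(2.0, 0.5)
        out = g.settlement_demand(ledger, self.settlements([123]))
        assert out.settlement_table["grazing_demand"].iloc[0] == pytest.approx(1.5e9)

    def test_zero_weight_district_with_demand_raises(self):
        ledger = ledger_frame(1.0, 0.0)
        with pytest.raises(ValidationError):
            g.settlement_demand(ledger, self.settlements([0, 0]))


def test_merge_goats_combines_species():
    counts = pd.DataFrame(
        [
            {"district_id": 1, "species": "sheep", "farm_type": "HH", "head": 70},
            {"district_id": 1, "species": "goats", "farm_type": "HH", "head": 30},
            {"district_id": 1, "species": "cattle", "farm_type": "HH", "head": 5},
        ]
    )
    out = g.merge_goats(counts).set_index("species")["head"]
    assert out["sheep_goats"] == 100
    assert out["cattle"] == 5


def test_pipeline_demand_linear_in_livestock(country_bundle):
    """Scaling every head count by c scales every nutritive demand by c
    (the grazing remainder is then demand minus the unchanged fodder)."""
    import dataclasses

    base = g.compute_demand(country_bundle).district_table
    scaled_bundle = dataclasses.replace(
        country_bundle,
        livestock_counts=country_bundle.livestock_counts.assign(
            head=country_bundle.livestock_counts["head"] * 3
        ),
    )
    scaled = g.compute_demand(scaled_bundle).district_table
    keys = ["district_id", "species", "farm_type"]
    merged = base.merge(scaled, on=keys, suffixes=("_base", "_x3"))
    np.testing.assert_allclose(
        merged["total_demand_x3"], merged["total_demand_base"] * 3, rtol=1e-9
    )
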