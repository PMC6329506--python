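"""Pasture-use productivity and production-expansion scenarios.

Two questions follow from a calibrated grazing map: how productive is the
pasture that *is* used (meat and milk output per unit utilized area), and how
much more could be produced if currently unutilized pasture near settlements
were brought into use?  Expansion is assessed for land within 10 km (a
conservative reach) or 20 km of any settlement, either at the calibrated
business-as-usual (BAU) district off-take rates or at the maximum sustainable
rate (30% of total NPP).  Additional energy is converted to product along two
labelled paths — area × per-area yield, and energy ÷ per-head requirement ×
per-head product — because the two give genuinely different answers and the
choice matters; beef and milk figures are either-or uses of the same resource.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .allocation import AllocationResult, GroupSpec, run_allocation
from .calibration import OfftakeAssignment
from .errors import ValidationError
from .grid import DistrictRaster
from .supply import SupplyRaster, UsableClass

#: fraction of cattle classified as dairy, by farm type
DEFAULT_DAIRY_FRACTIONS = {"AE": 0.40, "PF": 0.50, "HH": 0.85}


@dataclass(frozen=True)
class ScenarioConfig:
    """Expansion-scenario knobs: settlement reach, off-take mode and dairy split."""

    settlement_radius_km: float = 10.0
    offtake_mode: str = "BAU"  # "BAU" (calibrated district rates) or "max"
    max_rate: float = 0.30
    dairy_fractions: dict = field(default_factory=lambda: dict(DEFAULT_DAIRY_FRACTIONS))
    #: species/farm type assumed for the additional stock
    expansion_species: str = "cattle"
    expansion_farm_type: str = "AE"

    def __post_init__(self) -> None:
        if not self.settlement_radius_km > 0:
            raise ValidationError("settlement radius must be > 0")
        if self.offtake_mode not in ("BAU", "max"):
            raise ValidationError("offtake_mode must be 'BAU' or 'max'")


@dataclass
class ScenarioResult:
    """Additional resource and production under one expansion scenario."""

    radius_km: float
    mode: str
    additional_area_km2: float
    additional_energy_mj: float
    #: tons of product by conversion path: {"area_yield": …, "energy_per_head": …}
    additional_beef_t: dict
    additional_milk_t: dict
    pct_increase_beef: dict
    pct_increase_milk: dict


def utilized_area_by_group(result: AllocationResult) -> pd.DataFrame:
    """Utilized pasture area (km²) per species × farm type from claim counts."""
    s = result.group_stats
    out = s.groupby(["species", "farm_type"], as_index=False)["n_pixels"].sum()
    out["area_km2"] = out["n_pixels"] * result.grid.cell_area / 1e6
    return out[["species", "farm_type", "area_km2"]]


def productivity_table(
    production: pd.DataFrame,
    utilized_area: pd.DataFrame,
    dairy_fractions: dict | None = None,
    area_basis_km2: float = 1.0,
) -> pd.DataFrame:
    """Meat and milk yield per unit utilized pasture area.

    ``production`` columns: species, farm_type, meat_t, milk_t.
    ``utilized_area`` columns: species, farm_type, area_km2.
    Meat yield = meat / area; milk yield (cattle only) divides by the
    dairy-adjusted area ``area × dairy_fraction(farm_type)``, a rough estimate
    of the share of pasture used by dairy animals.  ``area_basis_km2`` rescales
    the denominator unit (1 → t/km², 1000 → t per thousand km²).
    """
    dairy_fractions = dairy_fractions or dict(DEFAULT_DAIRY_FRACTIONS)
    t = production.merge(utilized_area, on=["species", "farm_type"], how="left")
    bad = t[(t["meat_t"] > 0) & ~(t["area_km2"] > 0)]
    if not bad.empty:
        raise ValidationError(
            f"nonzero production with zero utilized area: {bad[['species', 'farm_type']].to_dict('records')}"
        )
    t["meat_yield"] = np.where(
        t["area_km2"] > 0, t["meat_t"] / t["area_km2"] * area_basis_km2, 0.0
    )
    dairy_frac = t["farm_type"].map(dairy_fractions).astype(float)
    milk_area = np.where(
        t["species"] == "cattle", t["area_km2"] * dairy_frac, t["area_km2"]
    )
    t["milk_yield"] = np.where(milk_area > 0, t["milk_t"] / milk_area * area_basis_km2, 0.0)
    return t[["species", "farm_type", "area_km2", "meat_t", "meat_yield", "milk_t", "milk_yield"]]


def _distance_to_nearest_settlement(grid, settlements: pd.DataFrame) -> np.ndarray:
    """Per-pixel (flat) Euclidean distance in metres from the cell center to the
    nearest settlement of any size."""
    xx, yy = grid.cell_centers()
    tree = cKDTree(np.column_stack([settlements["x"], settlements["y"]]))
    d, _ = tree.query(np.column_stack([xx, yy]), k=1)
    return d


def landscape_partition(
    result: AllocationResult,
    supply: SupplyRaster,
    settlements: pd.DataFrame,
    radius_km: float,
) -> dict[str, np.ndarray]:
    """Partition all pixels into excluded / claimed / additional (unclaimed
    usable within the radius) / out_of_range (unclaimed usable beyond it)."""
    excluded = (supply.usable == int(UsableClass.EXCLUDED)).ravel()
    claimed = result.claimed_mask().ravel()
    d = _distance_to_nearest_settlement(supply.grid, settlements)
    within = d <= radius_km * 1000.0
    usable_unclaimed = ~excluded & ~claimed
    return {
        "excluded": excluded,
        "claimed": claimed,
        "additional": usable_unclaimed & within,
        "out_of_range": usable_unclaimed & ~within,
    }


def expansion_potential(
    result: AllocationResult,
    supply: SupplyRaster,
    settlements: pd.DataFrame,
    assignment: OfftakeAssignment,
    district_raster: DistrictRaster,
    config: ScenarioConfig,
    productivity: pd.DataFrame,
    per_head: pd.DataFrame,
    baseline_beef_t: float,
    baseline_milk_t: float,
    demand_table: pd.DataFrame | None = None,
    groups: tuple[GroupSpec, ...] | None = None,
) -> ScenarioResult:
    """Compute one expansion scenario.

    BAU mode: pixels left unclaimed by the calibrated run, within the settlement
    radius, yield energy at their own district's calibrated rate.  Max mode: the
    allocation is re-run at the uniform maximum sustainable rate (which frees
    land), and the resulting unclaimed pixels within the radius yield energy at
    that rate; this requires ``demand_table``.

    ``productivity`` is the output of :func:`productivity_table` (t/km² basis);
    ``per_head`` columns: species, farm_type, grazing_mj_per_head,
    meat_kg_per_head, milk_kg_per_head.
    """
    if assignment is None:
        raise ValidationError("an off-take assignment is required")
    grid = supply.grid

    if config.offtake_mode == "max":
        if demand_table is None:
            raise ValidationError("max mode needs the demand table to re-run the allocation")
        base = run_allocation(supply, settlements, demand_table, config.max_rate, groups)
        rate_flat = np.full(grid.n_pixels, config.max_rate)
    else:
        base = result
        lut = {
            r.district_id: (
                float(r.rate) if np.isfinite(r.rate) else assignment.config.default_rate
            )
            for r in assignment.table.itertuples()
        }
        did = district_raster.district_id.ravel()
        rate_flat = np.array(
            [lut.get(int(d), assignment.config.default_rate) for d in np.unique(did)]
        )[np.searchsorted(np.unique(did), did)]

    parts = landscape_partition(base, supply, settlements, config.settlement_radius_km)
    add = parts["additional"]
    pixel_energy = supply.pixel_energy().ravel()
    additional_area_km2 = float(np.count_nonzero(add) * grid.cell_area / 1e6)
    additional_energy = float((rate_flat[add] * pixel_energy[add]).sum())

    sp, ft = config.expansion_species, config.expansion_farm_type
    prow = productivity[(productivity["species"] == sp) & (productivity["farm_type"] == ft)]
    hrow = per_head[(per_head["species"] == sp) & (per_head["farm_type"] == ft)]
    if prow.empty or hrow.empty:
        raise ValidationError(f"no productivity/per-head entry for {sp}/{ft}")

    beef, milk = {}, {}
    beef["area_yield"] = additional_area_km2 * float(prow["meat_yield"].iloc[0])
    dairy_frac = config.dairy_fractions.get(ft, 1.0)
    milk["area_yield"] = additional_area_km2 * dairy_frac * float(prow["milk_yield"].iloc[0])

    heads = additional_energy / float(hrow["grazing_mj_per_head"].iloc[0])
    beef["energy_per_head"] = heads * float(hrow["meat_kg_per_head"].iloc[0]) / 1000.0
    milk["energy_per_head"] = heads * float(hrow["milk_kg_per_head"].iloc[0]) / 1000.0

    pct_beef = {k: (100.0 * v / baseline_beef_t if baseline_beef_t > 0 else np.nan) for k, v in beef.items()}
    pct_milk = {k: (100.0 * v / baseline_milk_t if baseline_milk_t > 0 else np.nan) for k, v in milk.items()}

    return ScenarioResult(
        radius_km=config.settlement_radius_km,
        mode=config.offtake_mode,
        additional_area_km2=additional_area_km2,
        additional_energy_mj=additional_energy,
        additional_beef_t=beef,
        additional_milk_t=milk,
        pct_increase_beef=pct_beef,
        pct_increase_milk=pct_milk,
    )
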