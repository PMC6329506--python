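"""District off-take rate calibration via the 10-km median grazing-distance rule.

The uniform-rate sensitivity sweep runs the full allocation under each of
eleven off-take rates (10%–60% in 5% steps).  For every district, the lowest
rate at which the *median* maximum grazing distance of household cattle (the
group most tied to its settlement) over the district's grazing settlements
falls below 10 km becomes the district's calibrated rate.  Districts without
household cattle fall back to household sheep-goats; districts with neither
have no household grazing stock and receive no calibrated rate (a configurable
default applies in the final run).  Districts that fail the criterion even at
60% keep the ceiling rate.  The model is then re-run with every settlement
carrying its own district's rate wherever it grazes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allocation import AllocationResult, GroupSpec, run_allocation
from .errors import ValidationError
from .supply import SupplyRaster

DEFAULT_RATE_GRID = tuple(round(0.10 + 0.05 * i, 2) for i in range(11))  # 0.10 … 0.60


@dataclass(frozen=True)
class CalibrationConfig:
    """Sweep grid and distance rule for the off-take calibration."""

    rate_grid: tuple[float, ...] = DEFAULT_RATE_GRID
    distance_threshold_km: float = 10.0
    reference_species: str = "cattle"
    fallback_species: str = "sheep_goats"
    reference_farm_type: str = "HH"
    #: rate used in the calibrated run for districts with no household stock
    default_rate: float = 0.10

    def __post_init__(self) -> None:
        grid = tuple(self.rate_grid)
        if list(grid) != sorted(set(grid)):
            raise ValidationError("rate_grid must be strictly increasing")
        if not self.distance_threshold_km > 0:
            raise ValidationError("distance threshold must be > 0")


@dataclass
class OfftakeAssignment:
    """Calibrated off-take rate per district.

    ``table`` columns: district_id, rate (NaN where provenance is ``none``),
    provenance in {reference, fallback, ceiling, none}, median_distance_km at
    the assigned rate (NaN for ``none``).
    """

    table: pd.DataFrame
    config: CalibrationConfig

    def rate_for(self, district_id) -> float:
        t = self.table
        row = t[t["district_id"] == district_id]
        if row.empty or not np.isfinite(row["rate"].iloc[0]):
            return self.config.default_rate
        return float(row["rate"].iloc[0])

    def settlement_rates(self, settlements: pd.DataFrame) -> dict:
        """Map settlement id → its district's calibrated (or default) rate."""
        lut = {
            r.district_id: (float(r.rate) if np.isfinite(r.rate) else self.config.default_rate)
            for r in self.table.itertuples()
        }
        return {
            s.settlement_id: lut.get(s.district_id, self.config.default_rate)
            for s in settlements.itertuples()
        }


def _reference_distances(
    result: AllocationResult, settlements: pd.DataFrame, species: str, farm_type: str
) -> pd.DataFrame:
    """Per-settlement max distance for one group, with district ids attached.

    Only settlements with positive demand for the group appear (the median is
    taken over grazing settlements)."""
    s = result.group_stats
    sub = s[(s["species"] == species) & (s["farm_type"] == farm_type) & (s["demand_mj"] > 0)]
    return sub.merge(settlements[["settlement_id", "district_id"]], on="settlement_id")[
        ["settlement_id", "district_id", "max_distance_km"]
    ]


def run_rate_sweep(
    supply: SupplyRaster,
    settlements: pd.DataFrame,
    demand_table: pd.DataFrame,
    config: CalibrationConfig | None = None,
    groups: tuple[GroupSpec, ...] | None = None,
    keep_results: bool = False,
) -> dict:
    """Run the full allocation at every rate in the grid.

    Returns ``{rate: {"distances": {(species, farm_type): frame}, "area_km2": float,
    "result": AllocationResult | None}}``.  Results are discarded by default to
    bound memory; the per-settlement reference distances and utilized area are
    all the calibration needs.
    """
    config = config or CalibrationConfig()
    sweep: dict = {}
    for rate in config.rate_grid:
        res = run_allocation(supply, settlements, demand_table, rate, groups)
        distances = {
            (sp, config.reference_farm_type): _reference_distances(
                res, settlements, sp, config.reference_farm_type
            )
            for sp in (config.reference_species, config.fallback_species)
        }
        sweep[rate] = {
            "distances": distances,
            "area_km2": res.utilized_area_km2(),
            "result": res if keep_results else None,
        }
    return sweep


def assignment_from_sweep(
    sweep: dict,
    settlements: pd.DataFrame,
    demand_table: pd.DataFrame,
    config: CalibrationConfig | None = None,
) -> OfftakeAssignment:
    """Pure selection step: pick each district's lowest qualifying rate from the
    sweep outputs (independent of the order the sweeps were run in)."""
    config = config or CalibrationConfig()
    ft = config.reference_farm_type

    def districts_with(species: str, grazing_only: bool) -> set:
        sub = demand_table[
            (demand_table["species"] == species) & (demand_table["farm_type"] == ft)
        ]
        if grazing_only:
            sub = sub[sub["grazing_demand"] > 0]
        with_district = sub[["settlement_id"]].merge(
            settlements[["settlement_id", "district_id"]], on="settlement_id"
        )
        return set(with_district["district_id"])

    # a district participates if it holds the group at all; the median is taken
    # over its *grazing* settlements (zero-demand ones graze at distance 0, so a
    # district whose whole group is fodder-covered gets the grid minimum)
    ref_any = districts_with(config.reference_species, grazing_only=False)
    ref_pos = districts_with(config.reference_species, grazing_only=True)
    fb_any = districts_with(config.fallback_species, grazing_only=False) - ref_any
    fb_pos = districts_with(config.fallback_species, grazing_only=True) - ref_any
    all_districts = sorted(set(settlements["district_id"]))

    rows = []
    for d in all_districts:
        if d in ref_any:
            species, provenance, grazes = config.reference_species, "reference", d in ref_pos
        elif d in fb_any:
            species, provenance, grazes = config.fallback_species, "fallback", d in fb_pos
        else:
            rows.append(
                {"district_id": d, "rate": np.nan, "provenance": "none", "median_distance_km": np.nan}
            )
            continue
        if not grazes:
            rows.append(
                {
                    "district_id": d,
                    "rate": config.rate_grid[0],
                    "provenance": provenance,
                    "median_distance_km": 0.0,
                }
            )
            continue
        chosen = None
        median_at = np.nan
        for rate in config.rate_grid:
            dist = sweep[rate]["distances"][(species, ft)]
            med = float(dist.loc[dist["district_id"] == d, "max_distance_km"].median())
            if med < config.distance_threshold_km:
                chosen, median_at = rate, med
                break
        if chosen is None:
            chosen = config.rate_grid[-1]
            dist = sweep[chosen]["distances"][(species, ft)]
            median_at = float(dist.loc[dist["district_id"] == d, "max_distance_km"].median())
            provenance = "ceiling"
        rows.append(
            {
                "district_id": d,
                "rate": chosen,
                "provenance": provenance,
                "median_distance_km": median_at,
            }
        )
    return OfftakeAssignment(table=pd.DataFrame(rows), config=config)


def calibrate_offtake(
    supply: SupplyRaster,
    settlements: pd.DataFrame,
    demand_table: pd.DataFrame,
    config: CalibrationConfig | None = None,
    groups: tuple[GroupSpec, ...] | None = None,
) -> OfftakeAssignment:
    """Eleven-rate sweep + lowest-qualifying-rate selection per district."""
    config = config or CalibrationConfig()
    if demand_table["grazing_demand"].gt(0).any():
        with_demand = set(
            demand_table.loc[demand_table["grazing_demand"] > 0, "settlement_id"]
        )
        if not with_demand <= set(settlements["settlement_id"]):
            raise ValidationError("demand table references unknown settlements")
    sweep = run_rate_sweep(supply, settlements, demand_table, config, groups)
    return assignment_from_sweep(sweep, settlements, demand_table, config)


def run_calibrated(
    supply: SupplyRaster,
    settlements: pd.DataFrame,
    demand_table: pd.DataFrame,
    assignment: OfftakeAssignment,
    groups: tuple[GroupSpec, ...] | None = None,
) -> AllocationResult:
    """Re-run the allocation with per-settlement district rates (the variable-rate
    grazing-intensity map)."""
    rates = assignment.settlement_rates(settlements)
    return run_allocation(supply, settlements, demand_table, rates, groups)
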