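"""High-level orchestration: bundle → supply → demand → calibration → scenarios.

Each step is a thin composition of the module-level operations, so the CLI,
the tests and scripted analyses all exercise exactly the same code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .allocation import AllocationResult, GroupSpec
from .calibration import (
    CalibrationConfig,
    OfftakeAssignment,
    assignment_from_sweep,
    run_calibrated,
    run_rate_sweep,
)
from .demand import (
    DemandLedger,
    allocate_fodder,
    build_ledger,
    disaggregate_herd_ages,
    herd_energy_demand,
    merge_goats,
    settlement_demand,
)
from .scenarios import (
    ScenarioConfig,
    ScenarioResult,
    expansion_potential,
    productivity_table,
    utilized_area_by_group,
)
from .supply import SupplyRaster, build_supply
from .synthetic import ModelInputs

logger = logging.getLogger(__name__)


def build_supply_map(bundle: ModelInputs) -> SupplyRaster:
    """NPP + cover → grazing-energy supply raster."""
    return build_supply(bundle.npp, bundle.cover, bundle.supply_params)


def compute_demand(bundle: ModelInputs) -> DemandLedger:
    """Livestock statistics → district and settlement grazing demand."""
    counts = merge_goats(bundle.livestock_counts)
    ages = disaggregate_herd_ages(counts, bundle.census, bundle.districts)
    total = herd_energy_demand(ages, bundle.nutritive)
    fodder = allocate_fodder(
        bundle.fodder_production, bundle.fodder_shares, bundle.fodder_conversion, bundle.districts
    )
    ledger = build_ledger(total, fodder)
    return settlement_demand(ledger, bundle.settlements)


@dataclass
class PipelineResult:
    """Artifacts of a full model run on one input bundle."""

    supply: SupplyRaster
    ledger: DemandLedger
    sweep_areas_km2: dict
    assignment: OfftakeAssignment
    calibrated: AllocationResult
    scenarios: list[ScenarioResult] = field(default_factory=list)
    productivity: pd.DataFrame | None = None


def run_pipeline(
    bundle: ModelInputs,
    calibration: CalibrationConfig | None = None,
    scenario_configs: list[ScenarioConfig] | None = None,
    groups: tuple[GroupSpec, ...] | None = None,
) -> PipelineResult:
    """Full run: supply, demand, 11-rate sweep, calibration, variable-rate rerun
    and (optionally) expansion scenarios."""
    calibration = calibration or CalibrationConfig()
    supply = build_supply_map(bundle)
    ledger = compute_demand(bundle)
    table = ledger.settlement_table

    sweep = run_rate_sweep(supply, bundle.settlements, table, calibration, groups)
    assignment = assignment_from_sweep(sweep, bundle.settlements, table, calibration)
    calibrated = run_calibrated(supply, bundle.settlements, table, assignment, groups)

    area = utilized_area_by_group(calibrated)
    # groups that claimed no land (zero demand or exhausted landscape) cannot
    # have a per-area yield; drop them from the productivity table
    production = bundle.production.merge(area, on=["species", "farm_type"], how="left")
    missing = production[(production["meat_t"] > 0) & ~(production["area_km2"] > 0)]
    if not missing.empty:
        logger.warning(
            "no utilized area for %d producing groups; excluded from productivity: %s",
            len(missing),
            missing[["species", "farm_type"]].to_dict("records"),
        )
        production = production.drop(missing.index)
    productivity = productivity_table(
        production[["species", "farm_type", "meat_t", "milk_t"]], area
    )

    scenarios = []
    for sc in scenario_configs or []:
        scenarios.append(
            expansion_potential(
                calibrated,
                supply,
                bundle.settlements,
                assignment,
                bundle.district_raster,
                sc,
                productivity,
                bundle.per_head,
                baseline_beef_t=float(
                    bundle.production.loc[bundle.production["species"] == "cattle", "meat_t"].sum()
                ),
                baseline_milk_t=float(
                    bundle.production.loc[bundle.production["species"] == "cattle", "milk_t"].sum()
                ),
                demand_table=table,
                groups=groups,
            )
        )

    return PipelineResult(
        supply=supply,
        ledger=ledger,
        sweep_areas_km2={rate: sweep[rate]["area_km2"] for rate in sweep},
        assignment=assignment,
        calibrated=calibrated,
        scenarios=scenarios,
        productivity=productivity,
    )
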