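"""Grazing-energy demand: from district livestock statistics to settlement demand.

The demand side of the model works in annual metabolizable energy (MJ).  For
each district × species × farm type, livestock head counts are disaggregated
into herd age/function groups using province-level census proportions,
multiplied by per-head annual nutritive requirements, and reduced by the energy
supplied as fodder (allocated from district fodder production via province-level
consumption shares and fodder-unit energy conversions).  What remains must be
obtained by grazing; the ratio grazing/total demand is the *grazing gap*.
District grazing demand is finally split over the district's settlements with
population-based weights damped by a piecewise-linear livestock-owner fraction
(large towns hold proportionally far fewer livestock per resident).

Tabular conventions (pandas DataFrames):

``livestock_counts``   district_id, species, farm_type, head
``census``             province_id, species, age_group, head       (reference census)
``districts``          district_id, province_id
``nutritive``          species, age_group, farm_type, mj_per_head
``fodder_production``  district_id, farm_type, fodder_type, kg
``fodder_shares``      province_id, species, share
``fodder_conversion``  fodder_type, mj_per_kg
``settlements``        settlement_id, x, y, population, district_id
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

#: the three grazing species tracked by the model
GRAZING_SPECIES = ("cattle", "sheep_goats", "horses")
#: the three farm types: agricultural enterprise, private farm, household
FARM_TYPES = ("AE", "PF", "HH")

#: knots of the livestock-owner fraction vs settlement population
OWNER_FRACTION_KNOTS: tuple[tuple[float, float], ...] = (
    (0.0, 0.95),
    (1_000.0, 0.95),
    (5_000.0, 0.80),
    (10_000.0, 0.30),
    (50_000.0, 0.10),
    (1_000_000.0, 0.005),
)


def merge_goats(counts: pd.DataFrame, species_col: str = "species") -> pd.DataFrame:
    """Fold ``sheep`` and ``goats`` rows into the combined ``sheep_goats`` species.

    Goats are few and graze like sheep, so the model treats them as sheep before
    any computation.  Rows already labelled ``sheep_goats`` pass through.
    """
    out = counts.copy()
    out[species_col] = out[species_col].replace({"sheep": "sheep_goats", "goats": "sheep_goats"})
    group_cols = [c for c in out.columns if c not in ("head", "kg")]
    value_cols = [c for c in ("head", "kg") if c in out.columns]
    return out.groupby(group_cols, as_index=False)[value_cols].sum()


def disaggregate_herd_ages(
    livestock_counts: pd.DataFrame,
    census: pd.DataFrame,
    districts: pd.DataFrame,
) -> pd.DataFrame:
    """Split district head counts into herd age/function groups.

    The group share of each species in the district's province (from the
    reference census) is applied to the district total:

    ``head(g, d) = head(species, d) × head(g, province(d)) / head(species, province(d))``

    Returns a frame ``district_id, species, farm_type, age_group, head`` whose
    group sums reproduce the district totals exactly.
    """
    counts = livestock_counts.merge(districts[["district_id", "province_id"]], on="district_id")
    if len(counts) != len(livestock_counts):
        missing = set(livestock_counts.district_id) - set(districts.district_id)
        raise ValidationError(f"districts missing province mapping: {sorted(missing)}")
    if (counts["head"] < 0).any():
        raise ValidationError("negative livestock counts")

    totals = (
        census.groupby(["province_id", "species"], as_index=False)["head"]
        .sum()
        .rename(columns={"head": "census_total"})
    )
    shares = census.merge(totals, on=["province_id", "species"])
    shares["share"] = np.where(
        shares["census_total"] > 0, shares["head"] / shares["census_total"], np.nan
    )

    merged = counts.merge(
        shares[["province_id", "species", "age_group", "share"]],
        on=["province_id", "species"],
        how="left",
    )
    bad = merged[(merged["head"] > 0) & (~np.isfinite(merged["share"]))]
    if not bad.empty:
        names = sorted(bad["district_id"].unique().tolist())
        raise ValidationError(
            f"zero census total for species with nonzero district count in districts {names}"
        )
    merged["head"] = merged["head"] * merged["share"].fillna(0.0)
    return merged[["district_id", "species", "farm_type", "age_group", "head"]]


def herd_energy_demand(age_counts: pd.DataFrame, nutritive: pd.DataFrame) -> pd.DataFrame:
    """Annual energy demand in MJ per district × species × farm type.

    ``demand = Σ_groups head(g) × requirement(species, g, farm_type)``
    """
    merged = age_counts.merge(
        nutritive, on=["species", "age_group", "farm_type"], how="left", indicator=True
    )
    missing = merged[(merged["_merge"] != "both") & (merged["head"] > 0)]
    if not missing.empty:
        keys = missing[["species", "age_group", "farm_type"]].drop_duplicates()
        raise ConfigurationError(f"nutritive table missing entries:\n{keys.to_string(index=False)}")
    merged["total_demand"] = merged["head"] * merged["mj_per_head"].fillna(0.0)
    return merged.groupby(["district_id", "species", "farm_type"], as_index=False)[
        "total_demand"
    ].sum()


def allocate_fodder(
    fodder_production: pd.DataFrame,
    fodder_shares: pd.DataFrame,
    fodder_conversion: pd.DataFrame,
    districts: pd.DataFrame,
) -> pd.DataFrame:
    """Energy supplied by fodder in MJ per district × species × farm type.

    ``energy = kg(d, farm_type, fodder_type) × mj_per_kg(type) × share(species, province(d))``

    Shares for non-grazing consumers (pigs, poultry, camels…) divert energy away
    from the three grazing species; only cattle, sheep_goats and horses are
    retained in the output.
    """
    prod = fodder_production.merge(districts[["district_id", "province_id"]], on="district_id")
    conv = prod.merge(fodder_conversion, on="fodder_type", how="left", indicator=True)
    unknown = conv[conv["_merge"] != "both"]
    if not unknown.empty:
        raise ConfigurationError(
            f"unknown fodder types: {sorted(unknown['fodder_type'].unique().tolist())}"
        )
    conv["energy_mj"] = conv["kg"] * conv["mj_per_kg"]

    grazing_shares = fodder_shares[fodder_shares["species"].isin(GRAZING_SPECIES)]
    out = conv.merge(grazing_shares, on="province_id", how="inner")
    out["fodder_energy"] = out["energy_mj"] * out["share"]
    return out.groupby(["district_id", "species", "farm_type"], as_index=False)[
        "fodder_energy"
    ].sum()


@dataclass
class DemandLedger:
    """Demand bookkeeping at district and settlement level.

    ``district_table``: district_id, species, farm_type, total_demand,
    fodder_energy, grazing_demand, grazing_gap (all energies MJ).
    ``settlement_table``: settlement_id, district_id, species, farm_type,
    grazing_demand — filled by :func:`settlement_demand`.
    """

    district_table: pd.DataFrame
    settlement_table: pd.DataFrame | None = field(default=None)

    def national(self) -> dict[str, float]:
        """National aggregates: total demand, fodder energy, grazing demand (MJ) and gap."""
        t = self.district_table
        total = float(t["total_demand"].sum())
        fodder = float(np.minimum(t["fodder_energy"], t["total_demand"]).sum())
        grazing = float(t["grazing_demand"].sum())
        return {
            "total_demand_mj": total,
            "fodder_energy_mj": fodder,
            "grazing_demand_mj": grazing,
            "grazing_gap": grazing / total if total > 0 else 0.0,
        }


def build_ledger(total_demand: pd.DataFrame, fodder_energy: pd.DataFrame) -> DemandLedger:
    """Combine total demand and fodder energy into the demand ledger.

    Grazing demand is the non-negative remainder ``max(total − fodder, 0)``;
    surplus fodder is clamped.  The grazing gap is grazing/total demand (0 where
    there is no demand).
    """
    keys = ["district_id", "species", "farm_type"]
    t = total_demand.merge(fodder_energy, on=keys, how="outer").fillna(
        {"total_demand": 0.0, "fodder_energy": 0.0}
    )
    if (t["total_demand"] < 0).any() or (t["fodder_energy"] < 0).any():
        raise ValidationError("negative demand or fodder energy")
    t["grazing_demand"] = np.maximum(t["total_demand"] - t["fodder_energy"], 0.0)
    t["grazing_gap"] = np.where(
        t["total_demand"] > 0, t["grazing_demand"] / t["total_demand"], 0.0
    )
    return DemandLedger(district_table=t[keys + ["total_demand", "fodder_energy", "grazing_demand", "grazing_gap"]])


def owner_fraction(population) -> np.ndarray | float:
    """Fraction of residents who own livestock, as a function of settlement size.

    Piecewise linear over the knots in :data:`OWNER_FRACTION_KNOTS`; constant at
    0.95 up to 1,000 residents and at 0.005 beyond one million.
    """
    pop = np.asarray(population, dtype=float)
    if np.any(pop < 0):
        raise ValidationError("population must be non-negative")
    xs = np.array([k[0] for k in OWNER_FRACTION_KNOTS])
    ys = np.array([k[1] for k in OWNER_FRACTION_KNOTS])
    out = np.interp(pop, xs, ys)
    return float(out) if np.isscalar(population) else out


def settlement_demand(ledger: DemandLedger, settlements: pd.DataFrame) -> DemandLedger:
    """Split district grazing demand over settlements by damped population weight.

    ``weight_i = population_i × owner_fraction(population_i)``; each settlement
    receives the district's demand in proportion to its weight.  Conservation
    within a district is exact.  Returns a new ledger with ``settlement_table``
    populated.
    """
    s = settlements.copy()
    s["weight"] = s["population"].to_numpy(dtype=float) * owner_fraction(
        s["population"].to_numpy(dtype=float)
    )
    wsum = s.groupby("district_id")["weight"].sum().rename("district_weight")
    s = s.merge(wsum, on="district_id")

    dt = ledger.district_table
    demand_districts = set(dt.loc[dt["grazing_demand"] > 0, "district_id"])
    covered = set(s.loc[s["district_weight"] > 0, "district_id"])
    orphan = demand_districts - covered
    if orphan:
        raise ValidationError(
            f"districts with grazing demand but no positive settlement weight: {sorted(orphan)}"
        )

    merged = s.merge(dt, on="district_id")
    merged["grazing_demand"] = (
        merged["grazing_demand"] * merged["weight"] / merged["district_weight"]
    )
    table = merged[
        ["settlement_id", "district_id", "species", "farm_type", "grazing_demand"]
    ].sort_values(["settlement_id", "species", "farm_type"], ignore_index=True)
    return DemandLedger(district_table=dt, settlement_table=table)
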