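"""Synthetic landscapes and statistics with the structure the model assumes.

The generator builds a fully self-contained input bundle for the whole
pipeline: an NPP raster with a northeast→southwest productivity gradient and
multiplicative lognormal noise, a land-cover mosaic with spatially blocked
cropland in the productive north, a rectangular district partition grouped
into provinces, clustered settlements with heavy-tailed (lognormal)
populations, district livestock statistics derived from population via
per-capita holding rates, and the accompanying reference tables (herd age
census, nutritive requirements, fodder production/shares/conversions,
production statistics).  The nutritive, fodder and production tables are
*synthetic defaults*: plausible magnitudes for an extensive steppe livestock
system, supplied as data so real statistics can be dropped in unchanged.

Everything is driven by one seed through independent sub-streams, so bundles
are bit-reproducible and adding a component does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FixtureError, ValidationError
from .grid import CoverClass, CoverRaster, DistrictRaster, Grid, NPPRaster
from .supply import SupplyParams

#: herd age/function groups used by the synthetic census and nutritive tables
AGE_GROUPS = ("juvenile", "growing", "adult")

_DEFAULT_COVER = {
    "grassland": 0.62,
    "bare": 0.08,
    "cropland": 0.15,
    "forest": 0.07,
    "water": 0.04,
    "artificial": 0.02,
    "preserve": 0.02,
}

_DEFAULT_LIVESTOCK_PC = {
    ("cattle", "HH"): 0.20,
    ("cattle", "PF"): 0.08,
    ("cattle", "AE"): 0.05,
    ("sheep_goats", "HH"): 0.55,
    ("sheep_goats", "PF"): 0.25,
    ("sheep_goats", "AE"): 0.15,
    ("horses", "HH"): 0.06,
    ("horses", "PF"): 0.035,
    ("horses", "AE"): 0.02,
}

_DEFAULT_FODDER_PC = {
    ("hay", "HH"): 350.0,
    ("hay", "PF"): 100.0,
    ("hay", "AE"): 150.0,
    ("concentrate", "HH"): 10.0,
    ("concentrate", "PF"): 10.0,
    ("concentrate", "AE"): 40.0,
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic country.

    The defaults describe a ~40,000 km² steppe landscape (400×400 cells of
    500 m) with 12 districts in 2 provinces and 150 settlements; NPP runs from
    ``npp_low`` gC/m²/yr in the dry southwest corner to ``npp_high`` in the
    northeast, echoing a precipitation gradient.  Per-capita livestock rates
    put roughly 60% of stock in households and give a national grazing demand
    a few percent of the total supply energy, so calibrated off-take rates
    land mostly at the low end of the sweep grid.
    """

    seed: int = 0
    n_rows: int = 400
    n_cols: int = 400
    cell_size: float = 500.0
    npp_low: float = 30.0
    npp_high: float = 200.0
    noise_sd: float = 0.25
    cover_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_COVER))
    n_districts_x: int = 4
    n_districts_y: int = 3
    n_provinces: int = 2
    n_settlements: int = 150
    pop_median: float = 800.0
    pop_sigma: float = 1.2
    cluster_fraction: float = 0.4
    n_clusters: int = 6
    cluster_sd_km: float = 4.0
    livestock_per_capita: dict = field(default_factory=lambda: dict(_DEFAULT_LIVESTOCK_PC))
    fodder_kg_per_capita: dict = field(default_factory=lambda: dict(_DEFAULT_FODDER_PC))
    #: global multiplier on livestock head counts (used by recovery fixtures)
    livestock_scale: float = 1.0


@dataclass
class ModelInputs:
    """Everything the pipeline needs, in the in-memory forms the modules consume."""

    config: SynthConfig
    grid: Grid
    npp: NPPRaster
    cover: CoverRaster
    district_raster: DistrictRaster
    districts: pd.DataFrame  # district_id, province_id
    settlements: pd.DataFrame  # settlement_id, x, y, population, district_id
    livestock_counts: pd.DataFrame  # district_id, species, farm_type, head
    census: pd.DataFrame  # province_id, species, age_group, head
    nutritive: pd.DataFrame  # species, age_group, farm_type, mj_per_head
    fodder_production: pd.DataFrame  # district_id, farm_type, fodder_type, kg
    fodder_shares: pd.DataFrame  # province_id, species, share
    fodder_conversion: pd.DataFrame  # fodder_type, mj_per_kg
    production: pd.DataFrame  # species, farm_type, meat_t, milk_t
    per_head: pd.DataFrame  # species, farm_type, grazing_mj_per_head, meat/milk kg per head
    supply_params: SupplyParams


def _npp_field(cfg: SynthConfig, rng: np.random.Generator, grid: Grid) -> np.ndarray:
    rows = np.arange(cfg.n_rows) / max(cfg.n_rows - 1, 1)
    cols = np.arange(cfg.n_cols) / max(cfg.n_cols - 1, 1)
    # t = 1 at the NE corner (row 0, last col), 0 at the SW corner
    t = (cols[None, :] + (1.0 - rows[:, None])) / 2.0
    npp = cfg.npp_low + (cfg.npp_high - cfg.npp_low) * t
    if cfg.noise_sd > 0:
        # mean-preserving multiplicative lognormal noise
        noise = rng.lognormal(mean=-0.5 * cfg.noise_sd**2, sigma=cfg.noise_sd, size=grid.shape)
        npp = npp * noise
    return np.clip(npp, 0.0, None)


def _cover_field(cfg: SynthConfig, rng: np.random.Generator, grid: Grid) -> np.ndarray:
    fracs = dict(cfg.cover_fractions)
    total = sum(fracs.values())
    if not np.isclose(total, 1.0):
        raise ValidationError(f"cover fractions must sum to 1, got {total}")
    n = grid.n_pixels
    classes = np.zeros(grid.shape, dtype=np.int16)

    # cropland first, as contiguous blocks in the productive northern band
    n_crop = int(round(fracs.get("cropland", 0.0) * n))
    crop_mask = np.zeros(grid.shape, dtype=bool)
    if n_crop > 0:
        block = max(2, min(20, grid.n_rows // 4, grid.n_cols // 4))
        band_rows = max(block, grid.n_rows // 3)
        guard = 0
        while crop_mask.sum() < n_crop and guard < 10000:
            r0 = int(rng.integers(0, max(band_rows - block, 1)))
            c0 = int(rng.integers(0, max(grid.n_cols - block, 1)))
            crop_mask[r0 : r0 + block, c0 : c0 + block] = True
            guard += 1
        # trim overshoot row-major so the class count is exact
        flat = crop_mask.ravel()
        extra = int(flat.sum()) - n_crop
        if extra > 0:
            on = np.flatnonzero(flat)
            flat[on[-extra:]] = False
        crop_mask = flat.reshape(grid.shape)
    classes[crop_mask] = int(CoverClass.CROPLAND)

    # remaining classes sampled i.i.d. with renormalized fractions
    rest_names = [k for k in fracs if k != "cropland" and fracs[k] > 0]
    rest_p = np.array([fracs[k] for k in rest_names])
    rest_p = rest_p / rest_p.sum()
    codes = np.array([int(CoverClass[k.upper()]) for k in rest_names], dtype=np.int16)
    free = ~crop_mask
    draw = rng.choice(codes, size=int(free.sum()), p=rest_p)
    classes[free] = draw
    return classes


def _district_field(cfg: SynthConfig, grid: Grid) -> tuple[np.ndarray, pd.DataFrame]:
    by = np.minimum(
        (np.arange(grid.n_rows) * cfg.n_districts_y) // grid.n_rows, cfg.n_districts_y - 1
    )
    bx = np.minimum(
        (np.arange(grid.n_cols) * cfg.n_districts_x) // grid.n_cols, cfg.n_districts_x - 1
    )
    did = (by[:, None] * cfg.n_districts_x + bx[None, :]).astype(np.int32)
    ids = np.arange(cfg.n_districts_x * cfg.n_districts_y)
    province = (ids % cfg.n_districts_x) * cfg.n_provinces // cfg.n_districts_x
    districts = pd.DataFrame({"district_id": ids, "province_id": province})
    return did, districts


def _settlements(
    cfg: SynthConfig, rng: np.random.Generator, grid: Grid, district_field: np.ndarray
) -> pd.DataFrame:
    width = grid.n_cols * grid.cell_size
    height = grid.n_rows * grid.cell_size
    margin = 2 * grid.cell_size

    n_clustered = int(round(cfg.cluster_fraction * cfg.n_settlements))
    centers_x = rng.uniform(margin, width - margin, size=cfg.n_clusters)
    centers_y = rng.uniform(margin, height - margin, size=cfg.n_clusters)
    xs, ys = [], []
    if n_clustered:
        which = rng.integers(0, cfg.n_clusters, size=n_clustered)
        xs.append(centers_x[which] + rng.normal(0, cfg.cluster_sd_km * 1000, n_clustered))
        ys.append(centers_y[which] + rng.normal(0, cfg.cluster_sd_km * 1000, n_clustered))
    n_uniform = cfg.n_settlements - n_clustered
    xs.append(rng.uniform(margin, width - margin, size=n_uniform))
    ys.append(rng.uniform(margin, height - margin, size=n_uniform))
    x = np.clip(np.concatenate(xs), margin, width - margin) + grid.x_origin
    y = grid.y_origin - np.clip(np.concatenate(ys), margin, height - margin)

    pop = np.maximum(
        np.round(cfg.pop_median * np.exp(cfg.pop_sigma * rng.standard_normal(cfg.n_settlements))),
        10,
    ).astype(int)

    col = np.clip(((x - grid.x_origin) / grid.cell_size).astype(int), 0, grid.n_cols - 1)
    row = np.clip(((grid.y_origin - y) / grid.cell_size).astype(int), 0, grid.n_rows - 1)
    did = district_field[row, col]
    return pd.DataFrame(
        {
            "settlement_id": np.arange(1, cfg.n_settlements + 1),
            "x": x,
            "y": y,
            "population": pop,
            "district_id": did,
        }
    )


def _census(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    base = {"cattle": (0.20, 0.30, 0.50), "sheep_goats": (0.25, 0.30, 0.45), "horses": (0.15, 0.30, 0.55)}
    rows = []
    for p in range(cfg.n_provinces):
        for sp, props in base.items():
            jitter = rng.uniform(0.9, 1.1, size=len(props)) * np.asarray(props)
            jitter = jitter / jitter.sum()
            total = float(rng.integers(50_000, 500_000))
            for g, frac in zip(AGE_GROUPS, jitter):
                rows.append(
                    {"province_id": p, "species": sp, "age_group": g, "head": total * frac}
                )
    return pd.DataFrame(rows)


def _nutritive() -> pd.DataFrame:
    """Synthetic default annual metabolizable-energy requirements (MJ/head/yr).

    Adult baselines of roughly 26 GJ (cattle), 4.2 GJ (sheep/goats) and 33 GJ
    (horses) with age multipliers, and farm-type multipliers reflecting the
    higher growth-rate targets on enterprises.  Plausible for extensive steppe
    systems; replace with handbook values for real applications.
    """
    adult = {"cattle": 26_000.0, "sheep_goats": 4_200.0, "horses": 33_000.0}
    age_mult = {"juvenile": 0.40, "growing": 0.70, "adult": 1.00}
    ft_mult = {"AE": 1.15, "PF": 1.00, "HH": 0.90}
    rows = [
        {
            "species": sp,
            "age_group": g,
            "farm_type": ft,
            "mj_per_head": adult[sp] * age_mult[g] * ft_mult[ft],
        }
        for sp in adult
        for g in AGE_GROUPS
        for ft in ft_mult
    ]
    return pd.DataFrame(rows)


def _fodder_tables(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    shares = pd.DataFrame(
        [
            {"province_id": p, "species": sp, "share": sh}
            for p in range(cfg.n_provinces)
            for sp, sh in (
                ("cattle", 0.55),
                ("sheep_goats", 0.15),
                ("horses", 0.10),
                ("pigs_poultry", 0.20),
            )
        ]
    )
    conversion = pd.DataFrame(
        [{"fodder_type": "hay", "mj_per_kg": 6.0}, {"fodder_type": "concentrate", "mj_per_kg": 10.5}]
    )
    return shares, conversion


def _production_tables(livestock: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic production statistics from head counts × per-head yields."""
    meat_kg = {"cattle": 67.0, "sheep_goats": 9.0, "horses": 45.0}
    milk_kg = {"cattle": 1200.0, "sheep_goats": 0.2, "horses": 12.0}
    heads = livestock.groupby(["species", "farm_type"], as_index=False)["head"].sum()
    heads["meat_t"] = heads["head"] * heads["species"].map(meat_kg) / 1000.0
    heads["milk_t"] = heads["head"] * heads["species"].map(milk_kg) / 1000.0
    production = heads[["species", "farm_type", "meat_t", "milk_t"]]

    per_head = pd.DataFrame(
        [
            {
                "species": sp,
                "farm_type": ft,
                "grazing_mj_per_head": {"cattle": 16_500.0, "sheep_goats": 2_700.0, "horses": 22_000.0}[sp],
                "meat_kg_per_head": meat_kg[sp],
                "milk_kg_per_head": {"cattle": 2_300.0, "sheep_goats": 0.5, "horses": 60.0}[sp],
            }
            for sp in meat_kg
            for ft in ("AE", "PF", "HH")
        ]
    )
    return production, per_head


def generate(config: SynthConfig | None = None) -> ModelInputs:
    """Generate a complete, validated input bundle; deterministic under the seed."""
    cfg = config or SynthConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_npp, rng_cover, rng_settle, rng_stats = (np.random.default_rng(s) for s in streams)

    grid = Grid(cfg.n_rows, cfg.n_cols, cfg.cell_size, crs_label="synthetic-metric")
    npp = NPPRaster(grid, _npp_field(cfg, rng_npp, grid))
    cover = CoverRaster(grid, _cover_field(cfg, rng_cover, grid))
    district_field, districts = _district_field(cfg, grid)
    district_raster = DistrictRaster(grid, district_field)
    settlements = _settlements(cfg, rng_settle, grid, district_field)

    pop_by_district = settlements.groupby("district_id")["population"].sum()
    rows = []
    for did in districts["district_id"]:
        pop = float(pop_by_district.get(did, 0))
        for (sp, ft), rate in cfg.livestock_per_capita.items():
            rows.append(
                {
                    "district_id": did,
                    "species": sp,
                    "farm_type": ft,
                    "head": round(pop * rate * cfg.livestock_scale),
                }
            )
    livestock = pd.DataFrame(rows)

    usable = np.isin(
        cover.classes, [int(CoverClass.GRASSLAND), int(CoverClass.BARE), int(CoverClass.CROPLAND)]
    )
    if livestock["head"].sum() > 0 and not usable.any():
        raise ValidationError("infeasible config: livestock present but no grazeable pixels")

    fodder_rows = []
    for did in districts["district_id"]:
        pop = float(pop_by_district.get(did, 0))
        for (ftype, farm), kg_pc in cfg.fodder_kg_per_capita.items():
            fodder_rows.append(
                {"district_id": did, "farm_type": farm, "fodder_type": ftype, "kg": pop * kg_pc}
            )
    fodder_production = pd.DataFrame(fodder_rows)

    shares, conversion = _fodder_tables(cfg)
    production, per_head = _production_tables(livestock)

    return ModelInputs(
        config=cfg,
        grid=grid,
        npp=npp,
        cover=cover,
        district_raster=district_raster,
        districts=districts,
        settlements=settlements,
        livestock_counts=livestock,
        census=_census(cfg, rng_stats),
        nutritive=_nutritive(),
        fodder_production=fodder_production,
        fodder_shares=shares,
        fodder_conversion=conversion,
        production=production,
        per_head=per_head,
        supply_params=SupplyParams(),
    )


def recovery_config(seed: int = 0) -> SynthConfig:
    """Small single-district landscape used for calibration-recovery fixtures:
    four well-separated settlements holding only household cattle."""
    pc = {k: 0.0 for k in _DEFAULT_LIVESTOCK_PC}
    pc[("cattle", "HH")] = 0.25
    return SynthConfig(
        seed=seed,
        n_rows=120,
        n_cols=120,
        cell_size=500.0,
        npp_low=90.0,
        npp_high=140.0,
        noise_sd=0.05,
        cover_fractions={"grassland": 0.97, "cropland": 0.0, "water": 0.03},
        n_districts_x=1,
        n_districts_y=1,
        n_provinces=1,
        n_settlements=4,
        cluster_fraction=0.0,
        n_clusters=1,
        pop_median=2_000.0,
        pop_sigma=0.3,
        livestock_per_capita=pc,
        fodder_kg_per_capita={k: 0.0 for k in _DEFAULT_FODDER_PC},
    )


def _spread_settlements(bundle: ModelInputs, rng: np.random.Generator) -> None:
    """Pin the four fixture settlements near quarter points with small jitter so
    their 10-km disks never overlap (30 km separation on a 60 km grid)."""
    grid = bundle.grid
    w = grid.n_cols * grid.cell_size
    h = grid.n_rows * grid.cell_size
    anchors = [(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)]
    n = len(bundle.settlements)
    for i in range(n):
        fx, fy = anchors[i % 4]
        bundle.settlements.loc[i, "x"] = grid.x_origin + fx * w + rng.uniform(-1000, 1000)
        bundle.settlements.loc[i, "y"] = grid.y_origin - fy * h + rng.uniform(-1000, 1000)


def make_recovery_fixture(
    target_rate: float,
    config: SynthConfig | None = None,
    rate_grid: tuple[float, ...] | None = None,
    threshold_km: float = 10.0,
):
    """Build a bundle whose calibrated off-take rate is *known* to be ``target_rate``.

    Settlement demand is rescaled so that the household-cattle median maximum
    grazing distance is below ``threshold_km`` at ``target_rate`` but at or
    above it at the next-lower grid rate (for the grid minimum, any modest
    demand qualifies).  The bracketing is verified by actually running the two
    uniform-rate allocations; a :class:`FixtureError` is raised if no demand
    scale brackets the target.

    Returns ``(bundle, supply, settlements, demand_table)`` ready for
    :func:`grazemap.calibration.calibrate_offtake`.
    """
    from .calibration import DEFAULT_RATE_GRID
    from .allocation import run_allocation
    from .pipeline import build_supply_map, compute_demand

    grid_rates = tuple(rate_grid or DEFAULT_RATE_GRID)
    if target_rate not in grid_rates:
        raise ValidationError(f"target rate {target_rate} not on the rate grid")
    cfg = config or recovery_config()

    bundle = generate(cfg)
    _spread_settlements(bundle, np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[4]))
    supply = build_supply_map(bundle)
    ledger = compute_demand(bundle)
    base_table = ledger.settlement_table

    def median_at(scale: float, rate: float) -> float:
        table = base_table.copy()
        table["grazing_demand"] = table["grazing_demand"] * scale
        res = run_allocation(supply, bundle.settlements, table, rate)
        s = res.group_stats
        sub = s[(s["species"] == "cattle") & (s["farm_type"] == "HH") & (s["demand_mj"] > 0)]
        return float(sub["max_distance_km"].median())

    def crossing_scale(rate: float) -> float:
        """Smallest demand scale at which the median reaches the threshold."""
        lo, hi = 1e-3, 1.0
        while median_at(hi, rate) < threshold_km:
            lo, hi = hi, hi * 2
            if hi > 1e5:
                raise FixtureError("could not push the median past the threshold")
        while median_at(lo, rate) >= threshold_km:
            hi, lo = lo, lo / 2
            if lo < 1e-8:
                raise FixtureError("median exceeds threshold even at negligible demand")
        for _ in range(22):
            mid = 0.5 * (lo + hi)
            if median_at(mid, rate) >= threshold_km:
                hi = mid
            else:
                lo = mid
        return hi

    idx = grid_rates.index(target_rate)
    if idx == 0:
        scale = 0.5 * crossing_scale(target_rate)
    else:
        prev_rate = grid_rates[idx - 1]
        s_prev = crossing_scale(prev_rate)  # scale where prev rate starts failing
        s_tgt = crossing_scale(target_rate)  # scale where target starts failing
        if not s_prev < s_tgt:
            raise FixtureError(
                f"no demand scale brackets target rate {target_rate}: "
                f"prev crossing {s_prev:.4g} >= target crossing {s_tgt:.4g}"
            )
        scale = 0.5 * (s_prev + s_tgt)
        if not (median_at(scale, prev_rate) >= threshold_km > median_at(scale, target_rate)):
            raise FixtureError("bracket verification failed for the chosen demand scale")

    demand_table = base_table.copy()
    demand_table["grazing_demand"] = demand_table["grazing_demand"] * scale
    return bundle, supply, bundle.settlements, demand_table
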