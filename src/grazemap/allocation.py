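"""Competitive greedy allocation of settlement grazing demand onto the supply raster.

Livestock graze outward from their home settlement, and livestock of different
species and farm types differ in mobility.  The model expresses this as nine
ordered species × farm-type groups, each with a base search radius (2 km for
household/private-farm sheep-goats and cattle, 5 km for enterprise sheep-goats
and cattle, 10 km for horses).  Within a group, all settlements compete
simultaneously: allocation proceeds in rings (disks of radius k·r for
k = 1, 2, 3, …), and inside a ring settlements take turns round-robin in
ascending settlement-id order, each claiming its single best unclaimed pixel
per turn — highest energy density first, ties broken by distance to the
settlement and then by row-major pixel index.  A claimed pixel is removed from
play for every settlement and every later group (exclusive claims).  A pixel
yields ``off-take rate × pixel energy`` MJ; the last pixel a settlement claims
consumes only its residual demand, so energy is conserved exactly.  The ring
expands when no competing settlement can claim, and a group ends when all its
demands are met or the landscape is exhausted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import Grid
from .supply import SupplyRaster, UsableClass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSpec:
    """One of the nine allocation groups: distribution order, identity and base radius."""

    order_index: int
    species: str
    farm_type: str
    radius_km: float


def default_groups() -> tuple[GroupSpec, ...]:
    """The nine groups in their distribution order.

    Sheep and goats precede cattle within a farm type; households precede
    private farms precede enterprises; horses of all farm types go last (they
    graze farthest and overnight on pasture).
    """
    return (
        GroupSpec(1, "sheep_goats", "HH", 2.0),
        GroupSpec(2, "cattle", "HH", 2.0),
        GroupSpec(3, "sheep_goats", "PF", 2.0),
        GroupSpec(4, "cattle", "PF", 2.0),
        GroupSpec(5, "sheep_goats", "AE", 5.0),
        GroupSpec(6, "cattle", "AE", 5.0),
        GroupSpec(7, "horses", "HH", 10.0),
        GroupSpec(8, "horses", "PF", 10.0),
        GroupSpec(9, "horses", "AE", 10.0),
    )


@dataclass
class AllocationResult:
    """Output of a full allocation run.

    ``claim_settlement``/``claim_group`` map every pixel to its exclusive
    claimant (settlement id and group order index; -1/0 where unclaimed);
    ``consumed`` holds the energy actually eaten off each pixel (MJ).
    ``group_stats`` has one row per settlement × group with positive demand:
    demand, consumption, whether demand was met, the maximum grazing distance
    (km), pixels claimed and the final ring index reached.
    """

    grid: Grid
    claim_settlement: np.ndarray = field(repr=False)
    claim_group: np.ndarray = field(repr=False)
    consumed: np.ndarray = field(repr=False)
    group_stats: pd.DataFrame = field(repr=False)

    def claimed_mask(self) -> np.ndarray:
        return self.claim_group > 0

    def utilized_area_km2(self) -> float:
        """Total area of claimed pixels in km²."""
        return float(np.count_nonzero(self.claimed_mask()) * self.grid.cell_area / 1e6)

    def intensity(self, supply: SupplyRaster) -> np.ndarray:
        """Per-pixel grazing intensity: consumed energy / total pixel energy."""
        pixel_energy = supply.pixel_energy()
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(pixel_energy > 0, self.consumed / pixel_energy, 0.0)
        return out


class _SettlementState:
    """Per-settlement candidate queue for one allocation group."""

    __slots__ = (
        "sid",
        "x",
        "y",
        "remaining",
        "demand",
        "offtake",
        "cand_idx",
        "cand_d2",
        "cand_energy",
        "ptr",
        "max_d2",
        "n_pixels",
        "final_ring",
        "corner_d2",
    )

    def __init__(self, sid, x, y, demand, offtake, corner_d2):
        self.sid = sid
        self.x = x
        self.y = y
        self.demand = demand
        self.remaining = demand
        self.offtake = offtake
        self.cand_idx = np.empty(0, dtype=np.int64)
        self.cand_d2 = np.empty(0, dtype=float)
        self.cand_energy = np.empty(0, dtype=float)
        self.ptr = 0
        self.max_d2 = 0.0
        self.n_pixels = 0
        self.final_ring = 0
        self.corner_d2 = corner_d2


def _corner_d2(grid: Grid, x: float, y: float) -> float:
    """Squared distance from (x, y) to the farthest pixel *center* of the grid."""
    xs = (grid.x_origin + 0.5 * grid.cell_size, grid.x_origin + (grid.n_cols - 0.5) * grid.cell_size)
    ys = (grid.y_origin - 0.5 * grid.cell_size, grid.y_origin - (grid.n_rows - 0.5) * grid.cell_size)
    return max((x - cx) ** 2 + (y - cy) ** 2 for cx in xs for cy in ys)


def _annulus_candidates(
    grid: Grid,
    energy: np.ndarray,
    eligible: np.ndarray,
    x: float,
    y: float,
    r_in_m: float,
    r_out_m: float,
):
    """Flat indices, squared distances and energies of eligible pixels whose
    centers lie in the half-open annulus ``r_in < d <= r_out`` around (x, y)."""
    cs = grid.cell_size
    col_lo = max(0, int(math.floor((x - r_out_m - grid.x_origin) / cs - 0.5)))
    col_hi = min(grid.n_cols - 1, int(math.ceil((x + r_out_m - grid.x_origin) / cs - 0.5)))
    row_lo = max(0, int(math.floor((grid.y_origin - y - r_out_m) / cs - 0.5)))
    row_hi = min(grid.n_rows - 1, int(math.ceil((grid.y_origin - y + r_out_m) / cs - 0.5)))
    if col_lo > col_hi or row_lo > row_hi:
        empty = np.empty(0)
        return empty.astype(np.int64), empty, empty

    cols = np.arange(col_lo, col_hi + 1)
    rows = np.arange(row_lo, row_hi + 1)
    cx = grid.x_origin + (cols + 0.5) * cs
    cy = grid.y_origin - (rows + 0.5) * cs
    dx = cx - x
    dy = cy - y
    d2 = dy[:, None] ** 2 + dx[None, :] ** 2

    box = eligible[row_lo : row_hi + 1, col_lo : col_hi + 1]
    mask = (d2 <= r_out_m * r_out_m) & (d2 > r_in_m * r_in_m) & box
    rr, cc = np.nonzero(mask)
    idx = (rr + row_lo) * grid.n_cols + (cc + col_lo)
    return idx.astype(np.int64), d2[rr, cc], energy[rr + row_lo, cc + col_lo]


def allocate_group(
    supply: SupplyRaster,
    claimed: np.ndarray,
    claim_settlement: np.ndarray,
    claim_group: np.ndarray,
    consumed: np.ndarray,
    demands: dict,
    settlements: pd.DataFrame,
    spec: GroupSpec,
    offtake: dict,
) -> list[dict]:
    """Allocate one group's demands onto the shared claim state (mutated in place).

    ``claimed``/``claim_settlement``/``claim_group``/``consumed`` are flat
    (n_pixels,) arrays shared across the whole nine-group run.  ``demands`` maps
    settlement id → grazing demand (MJ) for this group; ``offtake`` maps
    settlement id → off-take rate in (0, 1].  Returns per-settlement stat dicts.
    """
    grid = supply.grid
    energy = supply.energy
    cell_area = grid.cell_area
    r_m = spec.radius_km * 1000.0

    eligible = (supply.usable != int(UsableClass.EXCLUDED)) & (energy > 0)
    energy_flat = energy.ravel()

    coords = settlements.set_index("settlement_id")
    states: list[_SettlementState] = []
    for sid in sorted(demands):
        d = float(demands[sid])
        if d < 0:
            raise ValidationError(f"negative demand for settlement {sid}")
        if d == 0:
            continue
        o = float(offtake[sid]) if isinstance(offtake, dict) else float(offtake)
        if not 0 < o <= 1:
            raise ValidationError(f"off-take rate for settlement {sid} must be in (0,1], got {o}")
        x = float(coords.at[sid, "x"])
        y = float(coords.at[sid, "y"])
        states.append(_SettlementState(sid, x, y, d, o, _corner_d2(grid, x, y)))

    stats: list[dict] = []

    def retire(st: _SettlementState, met: bool, ring: int) -> None:
        stats.append(
            {
                "settlement_id": st.sid,
                "species": spec.species,
                "farm_type": spec.farm_type,
                "order_index": spec.order_index,
                "demand_mj": st.demand,
                "consumed_mj": st.demand - st.remaining,
                "demand_met": met,
                "max_distance_km": math.sqrt(st.max_d2) / 1000.0,
                "n_pixels": st.n_pixels,
                "final_ring": ring,
            }
        )

    active = states
    k = 0
    while active:
        k += 1
        r_out = k * r_m
        for st in active:
            # merge ring-k annulus into the settlement's sorted candidate queue
            new_idx, new_d2, new_e = _annulus_candidates(
                grid, energy, eligible, st.x, st.y, (k - 1) * r_m, r_out
            )
            if st.ptr < len(st.cand_idx):
                keep = slice(st.ptr, len(st.cand_idx))
                new_idx = np.concatenate([st.cand_idx[keep], new_idx])
                new_d2 = np.concatenate([st.cand_d2[keep], new_d2])
                new_e = np.concatenate([st.cand_energy[keep], new_e])
            order = np.lexsort((new_idx, new_d2, -new_e))
            st.cand_idx = new_idx[order]
            st.cand_d2 = new_d2[order]
            st.cand_energy = new_e[order]
            st.ptr = 0

        # round-robin turns within the current ring
        while True:
            progress = False
            next_active: list[_SettlementState] = []
            for st in active:
                ptr = st.ptr
                cand = st.cand_idx
                n = len(cand)
                while ptr < n and claimed[cand[ptr]]:
                    ptr += 1
                st.ptr = ptr
                if ptr >= n:
                    next_active.append(st)
                    continue
                idx = cand[ptr]
                take = min(st.offtake * energy_flat[idx] * cell_area, st.remaining)
                claimed[idx] = True
                claim_settlement[idx] = st.sid
                claim_group[idx] = spec.order_index
                consumed[idx] = take
                st.remaining -= take
                st.n_pixels += 1
                if st.cand_d2[ptr] > st.max_d2:
                    st.max_d2 = st.cand_d2[ptr]
                st.ptr = ptr + 1
                progress = True
                if st.remaining <= 0:
                    retire(st, met=True, ring=k)
                else:
                    next_active.append(st)
            active = next_active
            if not progress or not active:
                break

        if active and all(r_out * r_out >= st.corner_d2 for st in active):
            # every remaining disk already covers the whole grid: exhausted
            for st in active:
                logger.warning(
                    "landscape exhausted: settlement %s group %s/%s left %.3g MJ unmet",
                    st.sid,
                    spec.species,
                    spec.farm_type,
                    st.remaining,
                )
                retire(st, met=False, ring=k)
            active = []

    return stats


def run_allocation(
    supply: SupplyRaster,
    settlements: pd.DataFrame,
    demand_table: pd.DataFrame,
    offtake,
    groups: tuple[GroupSpec, ...] | None = None,
) -> AllocationResult:
    """Run the full ordered nine-group allocation over a shared claim mask.

    Parameters
    ----------
    settlements
        Frame with settlement_id, x, y (projected metres), district_id, population.
    demand_table
        Settlement-level grazing demand: settlement_id, species, farm_type,
        grazing_demand (MJ) — e.g. ``DemandLedger.settlement_table``.
    offtake
        Scalar rate in (0, 1] applied to every settlement, or a mapping
        settlement id → rate (settlements keep their own district's rate
        wherever they graze).
    """
    groups = groups or default_groups()
    if [g.order_index for g in groups] != sorted(g.order_index for g in groups):
        raise ValidationError("group specs must be ordered by order_index")

    grid = supply.grid
    n = grid.n_pixels
    claimed = np.zeros(n, dtype=bool)
    claim_settlement = np.full(n, -1, dtype=np.int64)
    claim_group = np.zeros(n, dtype=np.int8)
    consumed = np.zeros(n, dtype=float)

    if isinstance(offtake, (int, float)):
        offtake_map = float(offtake)
    else:
        offtake_map = dict(offtake)

    all_stats: list[dict] = []
    for spec in groups:
        sub = demand_table[
            (demand_table["species"] == spec.species)
            & (demand_table["farm_type"] == spec.farm_type)
        ]
        demands = dict(zip(sub["settlement_id"], sub["grazing_demand"]))
        all_stats.extend(
            allocate_group(
                supply,
                claimed,
                claim_settlement,
                claim_group,
                consumed,
                demands,
                settlements,
                spec,
                offtake_map,
            )
        )

    columns = [
        "settlement_id",
        "species",
        "farm_type",
        "order_index",
        "demand_mj",
        "consumed_mj",
        "demand_met",
        "max_distance_km",
        "n_pixels",
        "final_ring",
    ]
    stats = pd.DataFrame(all_stats, columns=columns)
    return AllocationResult(
        grid=grid,
        claim_settlement=claim_settlement.reshape(grid.shape),
        claim_group=claim_group.reshape(grid.shape),
        consumed=consumed.reshape(grid.shape),
        group_stats=stats.sort_values(["order_index", "settlement_id"], ignore_index=True),
    )


def max_grazing_distance(
    result: AllocationResult, settlement_id, species: str, farm_type: str
) -> float:
    """Distance (km) from a settlement to the farthest pixel it claimed for a
    group; 0 if the group claimed nothing for that settlement."""
    s = result.group_stats
    row = s[
        (s["settlement_id"] == settlement_id)
        & (s["species"] == species)
        & (s["farm_type"] == farm_type)
    ]
    if row.empty:
        return 0.0
    return float(row["max_distance_km"].iloc[0])
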