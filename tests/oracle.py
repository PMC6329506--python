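"""Brute-force reference simulator for the competitive greedy allocation.

Written independently of :mod:`grazemap.allocation`: no candidate queues, no
annulus bookkeeping — every turn rescans the whole raster for the settlement's
best eligible pixel.  Usable only on tiny grids, which is the point: it is the
oracle the fast engine is checked against pixel-for-pixel.

Shared contract with the engine (not re-derived here): cell centers at
``x0 + (col + 0.5)·cs`` / ``y0 − (row + 0.5)·cs``, ring k admits squared
distances ≤ (k·r)², and pixels with zero energy are never claimable.
"""

from __future__ import annotations

import numpy as np


def oracle_allocate(
    grid,
    energy: np.ndarray,
    usable: np.ndarray,
    settlements: dict,
    groups: list,
    offtake,
):
    """Exhaustive simulation of the full multi-group allocation.

    Parameters
    ----------
    settlements
        {settlement_id: (x, y)}.
    groups
        Ordered list of dicts with keys order_index, radius_km, demands
        ({settlement_id: MJ}).
    offtake
        Scalar or {settlement_id: rate}.

    Returns (claim_sid, claim_grp, consumed, stats) where the first three are
    (n_rows, n_cols) arrays and stats maps (order_index, sid) to a dict with
    demand_met, max_d2 and n_pixels.
    """
    n_rows, n_cols = grid.n_rows, grid.n_cols
    cs = grid.cell_size
    area = cs * cs
    claim_sid = np.full((n_rows, n_cols), -1, dtype=int)
    claim_grp = np.zeros((n_rows, n_cols), dtype=int)
    consumed = np.zeros((n_rows, n_cols), dtype=float)
    stats = {}

    def rate_of(sid):
        return offtake[sid] if isinstance(offtake, dict) else offtake

    def d2_to(sid, r, c):
        sx, sy = settlements[sid]
        cx = grid.x_origin + (c + 0.5) * cs
        cy = grid.y_origin - (r + 0.5) * cs
        return (cx - sx) ** 2 + (cy - sy) ** 2

    def best_pixel(sid, max_d2):
        best = None
        for r in range(n_rows):
            for c in range(n_cols):
                if claim_sid[r, c] != -1 or claim_grp[r, c] != 0:
                    continue
                if not usable[r, c] or energy[r, c] <= 0:
                    continue
                d2 = d2_to(sid, r, c)
                if d2 > max_d2:
                    continue
                key = (-energy[r, c], d2, r * n_cols + c)
                if best is None or key < best[0]:
                    best = (key, r, c, d2)
        return best

    def grid_corner_d2(sid):
        sx, sy = settlements[sid]
        worst = 0.0
        for r in (0, n_rows - 1):
            for c in (0, n_cols - 1):
                cx = grid.x_origin + (c + 0.5) * cs
                cy = grid.y_origin - (r + 0.5) * cs
                worst = max(worst, (cx - sx) ** 2 + (cy - sy) ** 2)
        return worst

    for g in groups:
        r_m = g["radius_km"] * 1000.0
        remaining = {sid: d for sid, d in g["demands"].items() if d > 0}
        info = {
            sid: {"max_d2": 0.0, "n_pixels": 0, "demand_met": False} for sid in remaining
        }
        k = 0
        while remaining:
            k += 1
            ring_d2 = (k * r_m) ** 2
            while True:
                progress = False
                for sid in sorted(remaining):
                    found = best_pixel(sid, ring_d2)
                    if found is None:
                        continue
                    _, r, c, d2 = found
                    take = min(rate_of(sid) * energy[r, c] * area, remaining[sid])
                    claim_sid[r, c] = sid
                    claim_grp[r, c] = g["order_index"]
                    consumed[r, c] = take
                    remaining[sid] -= take
                    info[sid]["n_pixels"] += 1
                    info[sid]["max_d2"] = max(info[sid]["max_d2"], d2)
                    progress = True
                    if remaining[sid] <= 0:
                        info[sid]["demand_met"] = True
                        del remaining[sid]
                if not progress or not remaining:
                    break
            if remaining and all(ring_d2 >= grid_corner_d2(sid) for sid in remaining):
                break  # landscape exhausted for everyone still unmet
        for sid, rec in info.items():
            stats[(g["order_index"], sid)] = rec
    return claim_sid, claim_grp, consumed, stats
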