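"""Least-cost travel time over a friction surface (cost-distance engine).

Cells form an 8-connected graph. The cost of moving between neighbouring
cells i and j is the standard GIS cost-distance edge:

    cost_ij = d_ij * (t_i + t_j) / 2

where t is the cell's minutes-per-metre and d_ij is the centre-to-centre
distance (cell_size for cardinal moves, cell_size * sqrt(2) for diagonal
moves). The cumulative travel-time field is the multi-source shortest
path from the clinic cells; least-cost paths are recovered by
steepest-descent backtracking with a fixed neighbour order for
determinism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .friction import FrictionSurface
from .geodata import Clinic, GeodataError, GridSpec, Village

log = logging.getLogger(__name__)

# fixed backtracking order: N, NE, E, SE, S, SW, W, NW
_NEIGHBOUR_ORDER = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


class CostDistanceError(ValueError):
    pass


@dataclass
class TravelTimeField:
    """Cumulative minutes from the nearest source clinic to every cell."""

    grid: GridSpec
    minutes: np.ndarray = field(repr=False)
    sources: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def at(self, x: float, y: float) -> float:
        r, c = self.grid.snap(x, y)
        return float(self.minutes[r, c])


@dataclass
class LeastCostPath:
    cells: list[tuple[int, int]]
    total_minutes: float
    total_metres: float
    reachable: bool = True


def _edge_arrays(friction: FrictionSurface) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Undirected 8-neighbour edges as (row_idx, col_idx, cost) arrays."""
    t = friction.cell_time_per_m
    nr, nc = t.shape
    cs = friction.grid.cell_size
    idx = np.arange(nr * nc).reshape(nr, nc)
    rows, cols, costs = [], [], []
    # east, south, south-east, south-west cover all undirected pairs
    offsets = ((0, 1, cs), (1, 0, cs), (1, 1, cs * math.sqrt(2)),
               (1, -1, cs * math.sqrt(2)))
    for dr, dc, d in offsets:
        r0 = slice(0, nr - dr)
        r1 = slice(dr, nr)
        if dc >= 0:
            c0, c1 = slice(0, nc - dc), slice(dc, nc)
        else:
            c0, c1 = slice(-dc, nc), slice(0, nc + dc)
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        w = d * 0.5 * (t.reshape(-1)[a] + t.reshape(-1)[b])
        rows.append(a)
        cols.append(b)
        costs.append(w)
    return (np.concatenate(rows), np.concatenate(cols), np.concatenate(costs))


def _edge_cost(friction: FrictionSurface, a: tuple[int, int],
               b: tuple[int, int]) -> float:
    cs = friction.grid.cell_size
    d = cs * math.sqrt(2) if (a[0] != b[0] and a[1] != b[1]) else cs
    t = friction.cell_time_per_m
    return d * 0.5 * (t[a] + t[b])


def snap_sources(friction: FrictionSurface,
                 sources: list[Clinic]) -> list[tuple[str, tuple[int, int]]]:
    snapped = []
    for clinic in sources:
        try:
            rc = friction.grid.snap(clinic.x, clinic.y)
        except GeodataError as exc:
            raise CostDistanceError(
                f"source clinic {clinic.clinic_id} outside grid: {exc}"
            ) from exc
        cx, cy = friction.grid.cell_center(*rc)
        log.debug("snapped clinic %s to cell %s (moved %.1f m)",
                  clinic.clinic_id, rc, math.hypot(cx - clinic.x, cy - clinic.y))
        snapped.append((clinic.clinic_id, rc))
    return snapped


def cumulative_cost(friction: FrictionSurface,
                    sources: list[Clinic]) -> TravelTimeField:
    """Multi-source least-cost travel-time field over the friction surface.

    Each cell's value is the minimum cumulative travel time (minutes) from
    any source clinic; source cells are exactly zero.
    """
    if not sources:
        raise CostDistanceError("at least one source clinic is required")
    snapped = snap_sources(friction, sources)
    nr, nc = friction.grid.shape
    rows, cols, costs = _edge_arrays(friction)
    n = nr * nc
    graph = coo_matrix((costs, (rows, cols)), shape=(n, n)).tocsr()
    src_idx = [r * nc + c for _, (r, c) in snapped]
    minutes = dijkstra(graph, directed=False, indices=src_idx, min_only=True)
    return TravelTimeField(grid=friction.grid,
                           minutes=minutes.reshape(nr, nc),
                           sources=snapped)


def least_cost_path(field_: TravelTimeField, friction: FrictionSurface,
                    origin: tuple[float, float]) -> LeastCostPath:
    """Backtrack the least-cost route from an origin point to its source.

    Follows predecessors satisfying ``minutes[i] == minutes[j] +
    cost(i, j)`` (within 1e-9 relative slack); ties broken by the fixed
    neighbour order N, NE, E, SE, S, SW, W, NW.
    """
    r, c = field_.grid.snap(*origin)
    if not np.isfinite(field_.minutes[r, c]):
        return LeastCostPath(cells=[(r, c)], total_minutes=math.inf,
                             total_metres=math.inf, reachable=False)
    nr, nc = field_.grid.shape
    cells = [(r, c)]
    metres = 0.0
    cs = field_.grid.cell_size
    guard = nr * nc + 1
    while field_.minutes[cells[-1]] > 0 and len(cells) <= guard:
        cur = cells[-1]
        here = field_.minutes[cur]
        nxt = None
        for dr, dc in _NEIGHBOUR_ORDER:
            cand = (cur[0] + dr, cur[1] + dc)
            if not (0 <= cand[0] < nr and 0 <= cand[1] < nc):
                continue
            step = _edge_cost(friction, cur, cand)
            if abs(field_.minutes[cand] + step - here) <= 1e-9 * max(1.0, here):
                nxt = cand
                break
        if nxt is None:  # numerical dead end; should not happen
            raise CostDistanceError(
                f"backtracking stalled at cell {cur}"
            )
        metres += cs * math.sqrt(2) if (nxt[0] != cur[0] and nxt[1] != cur[1]) else cs
        cells.append(nxt)
    return LeastCostPath(cells=cells,
                         total_minutes=float(field_.minutes[r, c]),
                         total_metres=metres)


def village_travel_times(field_: TravelTimeField,
                         villages: list[Village]) -> pd.DataFrame:
    """Travel time (minutes) from each village to the nearest source.

    Returns a DataFrame with columns ``village_id`` and ``minutes``.
    """
    outside = []
    rows = []
    for v in villages:
        try:
            r, c = field_.grid.snap(v.x, v.y)
        except GeodataError:
            outside.append(v.village_id)
            continue
        rows.append((v.village_id, float(field_.minutes[r, c])))
    if outside:
        raise CostDistanceError(
            f"villages outside grid: {', '.join(outside)}"
        )
    return pd.DataFrame(rows, columns=["village_id", "minutes"])
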