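"""TOPMODEL topographic wetness index from a DEM.

The wetness index ln(a / tan beta) — upslope contributing area per unit
contour length over local slope — proxies each location's capacity to
receive and accumulate water (and leached pesticides) from upstream.  The
pipeline computes it at DEM resolution via single-direction (D8) flow
routing, then averages it per analysis cell and min-max normalises across
cells before it modulates the rainfall and insecticide scores.

Steps: exact pit filling (priority flood), D8 steepest-descent routing with
deterministic tie-breaks, flat resolution by breadth-first drainage toward
the nearest spill point, upslope-area accumulation in topological order.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass

import numpy as np

from .raster import Raster, minmax_normalize

__all__ = ["TerrainFields", "fill_pits", "d8_flow", "twi", "compute_terrain",
           "OUTLET", "D8_OFFSETS"]

#: D8 neighbour offsets (drow, dcol) in deterministic scan order
#: E, SE, S, SW, W, NW, N, NE — codes 0..7.  Ties resolve to the lowest code.
D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))

_D8_DIST = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2),
                     1.0, np.sqrt(2), 1.0, np.sqrt(2)])

#: flow_dir marker for cells draining off the raster (or into nodata).
OUTLET = -1
_NODIR = -2  # internal: unassigned / nodata

#: tan(beta) floor preventing an infinite index on flats.
SLOPE_FLOOR = 1e-3


@dataclass
class TerrainFields:
    """DEM-derived fields, all co-registered with the input DEM."""

    dem_filled: Raster
    slope: Raster       # radians
    tan_beta: Raster    # dimensionless downslope gradient
    flow_dir: Raster    # D8 code 0-7, OUTLET, or _NODIR on nodata
    flow_acc: Raster    # upslope contributing area incl. own pixel, m^2
    twi: Raster         # ln(a / tan beta)
    twi_norm: Raster    # min-max scaled to [0, 1] over valid pixels


def fill_pits(dem: Raster) -> Raster:
    """Raise closed depressions to their spill level (priority-flood).

    After filling, every valid pixel has a non-ascending D8 path to the
    raster boundary (or to a nodata edge); output >= input everywhere, and
    the operation is idempotent.  Filling is exact: no gradient epsilon is
    added, so plateaus may remain (resolved later by the flow router).
    """
    z = dem.values_masked()
    valid = np.isfinite(z)
    if not valid.any():
        raise ValueError("DEM contains no valid elevations")
    nr, nc = z.shape
    filled = np.full_like(z, np.nan)
    visited = np.zeros_like(valid)

    heap: list[tuple[float, int, int, int]] = []
    counter = 0  # FIFO tie-break keeps the flood deterministic

    def push(r: int, c: int, elev: float) -> None:
        nonlocal counter
        heapq.heappush(heap, (elev, counter, r, c))
        counter += 1

    # seed with every valid cell on the raster edge or adjacent to nodata
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            edge = r == 0 or c == 0 or r == nr - 1 or c == nc - 1
            if not edge:
                for dr, dc in D8_OFFSETS:
                    if not valid[r + dr, c + dc]:
                        edge = True
                        break
            if edge:
                visited[r, c] = True
                filled[r, c] = z[r, c]
                push(r, c, z[r, c])

    while heap:
        elev, _, r, c = heapq.heappop(heap)
        for dr, dc in D8_OFFSETS:
            rn, cn = r + dr, c + dc
            if 0 <= rn < nr and 0 <= cn < nc and valid[rn, cn] and not visited[rn, cn]:
                visited[rn, cn] = True
                filled[rn, cn] = max(z[rn, cn], elev)
                push(rn, cn, filled[rn, cn])

    out = dem.copy_with(filled, nodata=None)
    return out


def _steepest_descent(z: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel steepest strictly-descending D8 direction and its gradient.

    Returns (dir, grad); dir = _NODIR where no strictly lower valid
    neighbour exists (flat or pit bottom).
    """
    nr, nc = z.shape
    best_dir = np.full((nr, nc), _NODIR, dtype=np.int8)
    best_grad = np.zeros((nr, nc))
    for code, (dr, dc) in enumerate(D8_OFFSETS):
        grad = np.full((nr, nc), -np.inf)
        rs = slice(max(0, -dr), min(nr, nr - dr))
        cs = slice(max(0, -dc), min(nc, nc - dc))
        rs_n = slice(max(0, dr), min(nr, nr + dr))
        cs_n = slice(max(0, dc), min(nc, nc + dc))
        drop = z[rs, cs] - z[rs_n, cs_n]
        drop[~valid[rs_n, cs_n]] = -np.inf
        grad[rs, cs] = drop / _D8_DIST[code]
        better = valid & (grad > best_grad) & (grad > 0)
        best_dir[better] = code
        best_grad[better] = grad[better]
    return best_dir, best_grad


def d8_flow(dem_filled: Raster) -> tuple[Raster, Raster]:
    """D8 flow direction and accumulation on a pit-free DEM.

    Each pixel drains to its steepest strictly-lower neighbour (ties to the
    lowest D8 code in scan order E, SE, S, SW, W, NW, N, NE).  Pixels with no
    lower neighbour on the raster edge (or beside nodata) drain off-grid
    (``OUTLET``); interior plateau pixels drain along the plateau toward the
    nearest spill by breadth-first distance.  Accumulation is the upslope
    contributing area including the pixel itself, so total outflow across
    outlets equals the total valid area.
    """
    z = dem_filled.values_masked()
    valid = np.isfinite(z)
    nr, nc = z.shape
    flow_dir, grad = _steepest_descent(z, valid)

    edge = np.zeros_like(valid)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True
    # pixels beside nodata can also spill off the valid region
    if (~valid).any():
        pad = np.pad(valid, 1, constant_values=False)
        beside_nodata = np.zeros_like(valid)
        for dr, dc in D8_OFFSETS:
            beside_nodata |= ~pad[1 + dr:1 + dr + nr, 1 + dc:1 + dc + nc]
        edge |= beside_nodata

    undef = valid & (flow_dir == _NODIR)
    # plateau/pit-bottom pixels on a spill edge drain off-grid
    flow_dir[undef & edge] = OUTLET

    # resolve remaining flats: BFS over equal-elevation pixels from spill
    # sources (pixels of the flat already assigned a direction)
    remaining = valid & (flow_dir == _NODIR)
    if remaining.any():
        dist = np.full((nr, nc), -1, dtype=np.int64)
        queue: deque[tuple[int, int]] = deque()
        rr, cc = np.nonzero(remaining)
        flat_elev = z.copy()
        # sources: assigned pixels adjacent to a remaining flat pixel at equal z
        for r, c in zip(rr, cc):
            for dr, dc in D8_OFFSETS:
                rn, cn = r + dr, c + dc
                if (0 <= rn < nr and 0 <= cn < nc and valid[rn, cn]
                        and flow_dir[rn, cn] != _NODIR
                        and z[rn, cn] == z[r, c] and dist[rn, cn] < 0):
                    dist[rn, cn] = 0
                    queue.append((rn, cn))
        while queue:
            r, c = queue.popleft()
            for dr, dc in D8_OFFSETS:
                rn, cn = r + dr, c + dc
                if (0 <= rn < nr and 0 <= cn < nc and remaining[rn, cn]
                        and dist[rn, cn] < 0 and z[rn, cn] == flat_elev[r, c]):
                    dist[rn, cn] = dist[r, c] + 1
                    queue.append((rn, cn))
        rr, cc = np.nonzero(remaining)
        for r, c in zip(rr, cc):
            if dist[r, c] < 0:  # cannot happen on a filled DEM
                raise RuntimeError("unresolvable flat: DEM not pit-free?")
            for code, (dr, dc) in enumerate(D8_OFFSETS):
                rn, cn = r + dr, c + dc
                if (0 <= rn < nr and 0 <= cn < nc and valid[rn, cn]
                        and z[rn, cn] == z[r, c]
                        and 0 <= dist[rn, cn] < dist[r, c]):
                    flow_dir[r, c] = code
                    break

    # accumulation in topological order (Kahn) — also proves acyclicity
    pixel_area = dem_filled.pixel_area
    acc = np.where(valid, pixel_area, np.nan)
    indeg = np.zeros((nr, nc), dtype=np.int32)
    rr, cc = np.nonzero(valid & (flow_dir >= 0))
    targets_r = rr + np.array([D8_OFFSETS[d][0] for d in flow_dir[rr, cc]])
    targets_c = cc + np.array([D8_OFFSETS[d][1] for d in flow_dir[rr, cc]])
    np.add.at(indeg, (targets_r, targets_c), 1)
    queue = deque(zip(*np.nonzero(valid & (indeg == 0))))
    processed = 0
    n_valid = int(valid.sum())
    while queue:
        r, c = queue.popleft()
        processed += 1
        d = flow_dir[r, c]
        if d >= 0:
            rn, cn = r + D8_OFFSETS[d][0], c + D8_OFFSETS[d][1]
            acc[rn, cn] += acc[r, c]
            indeg[rn, cn] -= 1
            if indeg[rn, cn] == 0:
                queue.append((rn, cn))
    if processed != n_valid:
        raise RuntimeError("cycle in D8 flow graph (DEM not pit-free?)")

    dir_raster = dem_filled.copy_with(flow_dir.astype(np.int8))
    acc_raster = dem_filled.copy_with(acc)
    return dir_raster, acc_raster


def twi(dem_filled: Raster, flow_dir: Raster, flow_acc: Raster,
        slope_floor: float = SLOPE_FLOOR) -> tuple[Raster, Raster]:
    """Topographic wetness index ln(a / tan beta) and its [0,1] normalisation.

    ``a`` is the upslope area per unit contour length (contour length = one
    pixel width); ``tan beta`` is the downslope gradient toward the D8
    receiver, floored at ``slope_floor`` so plateaus stay finite.  The
    normalised index is min-max scaled over the valid region; a constant
    field maps to 0.5 everywhere.
    """
    z = dem_filled.values_masked()
    valid = np.isfinite(z)
    _, grad = _steepest_descent(z, valid)
    tan_beta = np.where(valid, np.maximum(grad, slope_floor), np.nan)
    a = flow_acc.values_masked() / dem_filled.dx
    index = np.where(valid, np.log(a / tan_beta), np.nan)
    return (dem_filled.copy_with(index),
            dem_filled.copy_with(minmax_normalize(index)))


def compute_terrain(dem: Raster, slope_floor: float = SLOPE_FLOOR) -> TerrainFields:
    """Full terrain stack: fill -> route -> accumulate -> wetness index."""
    filled = fill_pits(dem)
    flow_dir, flow_acc = d8_flow(filled)
    z = filled.values_masked()
    valid = np.isfinite(z)
    _, grad = _steepest_descent(z, valid)
    tan_beta = np.where(valid, np.maximum(grad, slope_floor), np.nan)
    index, index_norm = twi(filled, flow_dir, flow_acc, slope_floor=slope_floor)
    return TerrainFields(
        dem_filled=filled,
        slope=filled.copy_with(np.arctan(tan_beta)),
        tan_beta=filled.copy_with(tan_beta),
        flow_dir=flow_dir,
        flow_acc=flow_acc,
        twi=index,
        twi_norm=index_norm,
    )
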