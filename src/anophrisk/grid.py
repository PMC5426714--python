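"""Analysis grid and zonal aggregation.

The model scores risk on a regular grid of square cells (10 x 10 km by
default) laid over the study region in a projected CRS.  This module builds
that grid and populates the per-cell table: land-use area proportions
``sp_i`` from the categorical raster (or polygons), area-weighted monthly
climate means, the cell-mean topographic wetness index, village population
and below-poverty-line population sums, district-inherited ITN density, and
the reverse integration of cell values back to district summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from shapely.strtree import STRtree

from .raster import Raster

__all__ = ["GridSpec", "Grid", "build_grid", "landuse_proportions",
           "landuse_proportions_polygons", "zonal_mean", "villages_to_cells",
           "itn_to_cells", "cells_to_districts", "district_incidence"]

logger = logging.getLogger(__name__)


@dataclass
class GridSpec:
    """Grid layout: cell size (m) and the region polygon to cover.

    The origin snaps to multiples of ``cell_size`` (reproducible cell ids);
    a cell belongs to the grid iff its intersection with the region has
    positive area, so boundary-straddling cells are included.
    """

    region: Polygon
    cell_size: float = 10_000.0
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.region is None or self.region.is_empty or self.region.area == 0:
            raise ValueError("region polygon is empty")


class Grid:
    """The built analysis grid: cell geometry plus row/col bookkeeping.

    ``cells`` is a DataFrame in deterministic row-major order (north to
    south, west to east) with columns ``cell_id, row, col, geometry,
    region_area`` — ``region_area`` being the cell-region intersection area.
    """

    def __init__(self, spec: GridSpec, cells: pd.DataFrame,
                 x_origin: float, y_origin: float, n_cols: int) -> None:
        self.spec = spec
        self.cells = cells
        self.x_origin = x_origin   # west edge of column 0
        self.y_origin = y_origin   # north edge of row 0
        self.n_cols = n_cols
        self._pos = {(r, c): i for i, (r, c) in
                     enumerate(zip(cells["row"], cells["col"]))}

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def cell_size(self) -> float:
        return self.spec.cell_size

    def locate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Positional cell index for points; -1 where outside the grid.

        Cells are half-open: a point on a shared edge belongs to exactly one
        cell (the one east/south of the edge in index space).
        """
        cs = self.spec.cell_size
        col = np.floor((np.asarray(x, float) - self.x_origin) / cs).astype(int)
        row = np.floor((self.y_origin - np.asarray(y, float)) / cs).astype(int)
        out = np.full(col.shape, -1, dtype=int)
        flat = out.ravel()
        for i, rc in enumerate(zip(row.ravel(), col.ravel())):
            flat[i] = self._pos.get(rc, -1)
        return out

    def geometry(self, pos: int) -> Polygon:
        return self.cells["geometry"].iloc[pos]


def build_grid(spec: GridSpec) -> Grid:
    """Lay the cell grid over the region.

    Exactly the cells whose intersection with the region has positive area
    are kept, in row-major order.
    """
    cs = spec.cell_size
    xmin, ymin, xmax, ymax = spec.region.bounds
    x_origin = math.floor(xmin / cs) * cs
    y_origin = math.ceil(ymax / cs) * cs
    n_cols = math.ceil((xmax - x_origin) / cs)
    n_rows = math.ceil((y_origin - ymin) / cs)

    rows = []
    for r in range(n_rows):
        for c in range(n_cols):
            cell = box(x_origin + c * cs, y_origin - (r + 1) * cs,
                       x_origin + (c + 1) * cs, y_origin - r * cs)
            inter = cell.intersection(spec.region)
            if inter.area > 0:
                rows.append({"cell_id": r * n_cols + c, "row": r, "col": c,
                             "geometry": cell, "region_area": inter.area})
    if not rows:
        raise ValueError("region intersects no grid cell")
    cells = pd.DataFrame(rows)
    return Grid(spec, cells, x_origin, y_origin, n_cols)


def _pixel_positions(grid: Grid, raster: Raster) -> tuple[np.ndarray, np.ndarray]:
    """(cell positional index, valid mask) for every raster pixel."""
    xc, yc = raster.cell_centers()
    pos = grid.locate(xc.ravel(), yc.ravel())
    return pos, raster.valid_mask().ravel()


def landuse_proportions(grid: Grid, landuse: Raster) -> pd.DataFrame:
    """Area proportions ``sp_i`` of each land-use code per cell (raster path).

    sp_i = (pixels of code i in the cell) / (classified pixels in the cell);
    proportions sum to 1 for any cell with classified area.  A cell with no
    classified pixel gets NaN proportions and is logged (excluded downstream
    from the land-use scores).
    """
    pos, valid = _pixel_positions(grid, landuse)
    keep = (pos >= 0) & valid
    codes = np.unique(landuse.data.ravel()[keep]).astype(int)
    code_idx = {c: i for i, c in enumerate(codes)}
    n, k = len(grid), len(codes)
    counts = np.zeros((n, k))
    vals = landuse.data.ravel()[keep].astype(int)
    ci = np.fromiter((code_idx[v] for v in vals), dtype=int, count=len(vals))
    np.add.at(counts, (pos[keep], ci), 1.0)
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("%d cell(s) have no classified land-use pixels; "
                       "land-use scores will be missing there", int(empty.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        sp = counts / totals[:, None]
    sp[empty] = np.nan
    return pd.DataFrame(sp, columns=[f"sp_{c}" for c in codes],
                        index=grid.cells.index)


def landuse_proportions_polygons(grid: Grid, landuse: pd.DataFrame) -> pd.DataFrame:
    """``sp_i`` from a polygon land-use layer (columns ``code, geometry``).

    Exact-geometry alternative to the raster path; the denominator is the
    classified (covered) area within each cell.
    """
    codes = sorted(set(int(c) for c in landuse["code"]))
    code_idx = {c: i for i, c in enumerate(codes)}
    areas = np.zeros((len(grid), len(codes)))
    tree = STRtree(list(landuse["geometry"]))
    for i, cell in enumerate(grid.cells["geometry"]):
        for j in tree.query(cell, predicate="intersects"):
            geom = landuse["geometry"].iloc[j]
            a = cell.intersection(geom).area
            if a > 0:
                areas[i, code_idx[int(landuse["code"].iloc[j])]] += a
    totals = areas.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp = areas / totals[:, None]
    sp[totals == 0] = np.nan
    return pd.DataFrame(sp, columns=[f"sp_{c}" for c in codes],
                        index=grid.cells.index)


def zonal_mean(grid: Grid, raster: Raster) -> np.ndarray:
    """Area-weighted mean of valid raster pixels per cell (NaN if none).

    Pixels are assigned to the cell containing their center; with square,
    equal-area pixels this is the exact area weighting.
    """
    pos, valid = _pixel_positions(grid, raster)
    keep = (pos >= 0) & valid
    vals = raster.values_masked().ravel()[keep]
    sums = np.zeros(len(grid))
    counts = np.zeros(len(grid))
    np.add.at(sums, pos[keep], vals)
    np.add.at(counts, pos[keep], 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def villages_to_cells(grid: Grid, villages: pd.DataFrame
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Total and below-poverty-line population per cell from village points.

    Cells are half-open, so a village exactly on a shared edge is counted in
    exactly one cell and total population is conserved.
    """
    P = np.zeros(len(grid))
    P_poor = np.zeros(len(grid))
    if len(villages) == 0:
        return P, P_poor
    x = np.array([g.x for g in villages["geometry"]])
    y = np.array([g.y for g in villages["geometry"]])
    pos = grid.locate(x, y)
    inside = pos >= 0
    pop = villages["population"].to_numpy(float)
    poor = pop * villages["poverty_fraction"].to_numpy(float)
    np.add.at(P, pos[inside], pop[inside])
    np.add.at(P_poor, pos[inside], poor[inside])
    return P, P_poor


def assign_districts(grid: Grid, districts: pd.DataFrame) -> np.ndarray:
    """Dominant-area district index per cell (-1 if no overlap).

    A cell straddling districts goes to the one covering the larger share of
    it; ties resolve to the lowest district index (deterministic).
    """
    assign = np.full(len(grid), -1, dtype=int)
    tree = STRtree(list(districts["geometry"]))
    for i, cell in enumerate(grid.cells["geometry"]):
        best_area = 0.0
        for j in sorted(tree.query(cell, predicate="intersects")):
            a = cell.intersection(districts["geometry"].iloc[j]).area
            if a > best_area:
                best_area = a
                assign[i] = j
    return assign


def itn_to_cells(grid: Grid, districts: pd.DataFrame, P: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-person ITN density D per cell, inherited from its district.

    District population is the sum of cell populations assigned to it
    (dominant-area rule); every cell of a district inherits the district's
    per-capita density itn_count / population.  Cells in districts with zero
    population get D = 0 (logged).

    Returns (D, district index per cell).
    """
    assign = assign_districts(grid, districts)
    k = len(districts)
    pops = np.zeros(k)
    for j in range(k):
        pops[j] = P[assign == j].sum()
    D = np.zeros(len(grid))
    zero_pop = 0
    for j in range(k):
        mask = assign == j
        itn = float(districts["itn_count"].iloc[j])
        if pops[j] > 0:
            D[mask] = itn / pops[j]
        else:
            if itn > 0 and mask.any():
                zero_pop += 1
            D[mask] = 0.0
    if zero_pop:
        logger.warning("%d district(s) have ITNs but zero integrated "
                       "population; their cells get D=0", zero_pop)
    return D, assign


def cells_to_districts(grid: Grid, values: pd.DataFrame,
                       districts: pd.DataFrame) -> pd.DataFrame:
    """Area-weighted district means of per-cell values.

    Each district's value is the mean of cell values weighted by the
    cell-district intersection area; missing cell values are excluded from
    both numerator and weight.
    """
    out = {}
    tree = STRtree(list(grid.cells["geometry"]))
    inter_areas: list[list[tuple[int, float]]] = []
    for dgeom in districts["geometry"]:
        pairs = []
        for i in sorted(tree.query(dgeom, predicate="intersects")):
            a = dgeom.intersection(grid.cells["geometry"].iloc[i]).area
            if a > 0:
                pairs.append((i, a))
        inter_areas.append(pairs)
    for col in values.columns:
        v = values[col].to_numpy(float)
        dv = np.full(len(districts), np.nan)
        for j, pairs in enumerate(inter_areas):
            num = den = 0.0
            for i, a in pairs:
                if np.isfinite(v[i]):
                    num += v[i] * a
                    den += a
            if den > 0:
                dv[j] = num / den
        out[col] = dv
    res = pd.DataFrame(out)
    if "district_id" in districts.columns:
        res.insert(0, "district_id", districts["district_id"].to_numpy())
    return res


def district_incidence(districts: pd.DataFrame, district_pop: np.ndarray
                       ) -> np.ndarray:
    """Malaria incidence per district: confirmed cases / integrated population."""
    cases = districts["malaria_cases"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        inc = cases / district_pop
    inc[district_pop <= 0] = np.nan
    return inc
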