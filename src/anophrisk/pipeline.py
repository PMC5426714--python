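"""End-to-end risk pipeline: sub-models -> risk surfaces -> district summaries.

Combines the three sub-models into the risk surfaces

* Y11 = Y4 * Y10 — vulnerable hosts exposed to malaria vectors,
* Y12 = Y4 * Y7  — vectors exposed to insecticides (resistance risk),
* Y13 = Y12 * Y10 — vulnerable hosts exposed to potentially resistant
  vectors,

integrates cell values to districts, correlates the modeled presence with
district malaria incidence (Pearson), and produces smoothed display
surfaces by inverse-distance interpolation from cell centers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr
from shapely import contains_xy

from . import __version__
from .config import ModelParams, WeightTable, default_weight_table
from .geoio import write_geojson
from .grid import (Grid, GridSpec, build_grid, cells_to_districts,
                   district_incidence, itn_to_cells, landuse_proportions,
                   villages_to_cells, zonal_mean)
from .insecticide import insecticide_columns
from .raster import Raster, minmax_normalize, write_ascii_grid
from .suitability import suitability_columns
from .synth import Scenario, ScenarioSpec, generate_scenario
from .terrain import compute_terrain
from .vulnerability import vulnerability_columns

__all__ = ["compute_risks", "correlate_incidence", "idw_interpolate",
           "trend_surface", "run_pipeline", "PipelineResult"]

logger = logging.getLogger(__name__)

_Y_COLUMNS_SUMMARY = ["Y4", "Y5a", "Y5", "Y6", "Y7", "Y8a", "Y8b", "Y8",
                      "Y9", "Y10", "Y11", "Y12", "Y13"]


def compute_risks(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-cell risk products Y11, Y12, Y13 from Y4, Y7, Y10 columns.

    Missing components propagate to missing risks (NaN).
    """
    for col in ("Y4", "Y7", "Y10"):
        if col not in cells.columns:
            raise ValueError(f"cell table lacks required column {col}")
    y4 = cells["Y4"].to_numpy(float)
    y7 = cells["Y7"].to_numpy(float)
    y10 = cells["Y10"].to_numpy(float)
    y12 = y4 * y7
    return pd.DataFrame({"Y11": y4 * y10, "Y12": y12, "Y13": y12 * y10},
                        index=cells.index)


def correlate_incidence(district_y4: np.ndarray, district_incidence: np.ndarray
                        ) -> tuple[float, int]:
    """Pearson correlation between district presence means and incidence.

    Districts missing either value are dropped (count logged).  Returns
    (r, n_districts used); r is NaN when fewer than 3 districts remain or
    either vector has zero variance.
    """
    a = np.asarray(district_y4, float)
    b = np.asarray(district_incidence, float)
    keep = np.isfinite(a) & np.isfinite(b)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("correlation: %d district(s) dropped for missing values",
                    dropped)
    n = int(keep.sum())
    if n < 3:
        return float("nan"), n
    if np.ptp(a[keep]) == 0 or np.ptp(b[keep]) == 0:
        logger.warning("correlation undefined: zero variance")
        return float("nan"), n
    r, _ = pearsonr(a[keep], b[keep])
    return float(r), n


def idw_interpolate(centers: np.ndarray, values: np.ndarray,
                    points: np.ndarray, power: float = 2.0,
                    n_neighbors: int = 12) -> np.ndarray:
    """Inverse-distance-weighted estimate of ``values`` at ``points``.

    Uses the ``n_neighbors`` nearest of the ``centers``; a point coinciding
    with a center (distance < 1e-9) returns that center's value exactly.
    """
    tree = cKDTree(centers)
    k = min(n_neighbors, len(centers))
    dist, idx = tree.query(points, k=k)
    dist = np.atleast_2d(dist.reshape(-1, k))
    idx = np.atleast_2d(idx.reshape(-1, k))
    exact = dist[:, 0] < 1e-9
    with np.errstate(divide="ignore"):
        w = 1.0 / dist ** power
    w[exact] = 0.0
    wsum = w.sum(axis=1)
    est = (w * values[idx]).sum(axis=1) / np.where(wsum > 0, wsum, 1.0)
    est[exact] = values[idx[exact, 0]]
    return est


def trend_surface(grid: Grid, values: np.ndarray, resolution: float = 1000.0,
                  power: float = 2.0, n_neighbors: int = 12) -> Raster:
    """Smoothed display surface by inverse-distance weighting of cell values.

    IDW (power 2, 12 nearest cell centers by default) from cell centers onto
    a fine raster clipped to the region; at a cell center the surface equals
    the cell value exactly.  Display-only — never feeds statistics.
    """
    v = np.asarray(values, float)
    centers = np.array([[g.centroid.x, g.centroid.y]
                        for g in grid.cells["geometry"]])
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError("no non-missing cell values to interpolate")
    centers, v = centers[ok], v[ok]

    xmin, ymin, xmax, ymax = grid.spec.region.bounds
    nc = max(1, int(np.ceil((xmax - xmin) / resolution)))
    nr = max(1, int(np.ceil((ymax - ymin) / resolution)))
    out = Raster(np.full((nr, nc), np.nan), xmin, ymin + nr * resolution,
                 resolution, crs=grid.spec.crs)
    xc, yc = out.cell_centers()
    pts = np.column_stack([xc.ravel(), yc.ravel()])
    inside = contains_xy(grid.spec.region, pts[:, 0], pts[:, 1])

    est = idw_interpolate(centers, v, pts[inside], power=power,
                          n_neighbors=n_neighbors)
    flat = out.data.ravel()
    flat[inside] = est
    out.data = flat.reshape(nr, nc)
    return out


@dataclass
class PipelineResult:
    """Everything one model run produces."""

    grid: Grid
    cells: pd.DataFrame          # one row per cell, all Y columns
    districts: pd.DataFrame      # district summaries (area-weighted means)
    scenario: Scenario | None
    correlation_r: float
    correlation_n: int
    report: dict


def run_pipeline(scenario: Scenario | ScenarioSpec | None = None,
                 params: ModelParams | None = None,
                 weights: WeightTable | None = None,
                 cell_size: float = 10_000.0,
                 region=None,
                 out_dir: str | Path | None = None,
                 surfaces: tuple[str, ...] = (),
                 surface_resolution: float = 1000.0) -> PipelineResult:
    """Run the full model on a (synthetic) study region.

    Steps: terrain stack from the DEM; 10 km analysis grid over the region;
    zonal aggregation of land use, climate, wetness index, villages and
    districts into the cell table; sub-models 1-3; risk products; district
    integration; presence-incidence correlation; optional CSV/GeoJSON/raster
    outputs under ``out_dir`` (``surfaces`` names Y columns to interpolate
    and write as display rasters).
    """
    params = params or ModelParams()
    weights = weights or default_weight_table()
    if scenario is None:
        scenario = ScenarioSpec()
    if isinstance(scenario, ScenarioSpec):
        scenario = generate_scenario(scenario)

    terrain = compute_terrain(scenario.dem)
    if region is None:
        region = scenario.spec.region()
    grid = build_grid(GridSpec(region=region, cell_size=cell_size))

    # --- populate the cell table ---------------------------------------
    sp = landuse_proportions(grid, scenario.landuse)
    T = np.stack([zonal_mean(grid, r) for r in scenario.temperature])
    R = np.stack([zonal_mean(grid, r) for r in scenario.rainfall])
    # wetness index: cell mean of the pixel index, then min-max over cells
    twi_cell = zonal_mean(grid, terrain.twi)
    twi_norm = minmax_normalize(twi_cell)
    P, P_poor = villages_to_cells(grid, scenario.villages)
    D, district_of = itn_to_cells(grid, scenario.districts, P)

    cells = grid.cells[["cell_id", "row", "col"]].copy()
    cells["twi_norm"] = twi_norm
    cells["P"] = P
    cells["P_poor"] = P_poor
    cells["D"] = D
    cells["district"] = district_of
    for m in range(12):
        cells[f"T_{m + 1:02d}"] = T[m]
        cells[f"R_{m + 1:02d}"] = R[m]
    cells = pd.concat([cells, sp], axis=1)

    cells = pd.concat([
        cells,
        suitability_columns(sp, T, R, twi_norm, weights, params),
        insecticide_columns(sp, twi_norm, D, weights, params),
        vulnerability_columns(P, P_poor, D, params).set_axis(cells.index),
    ], axis=1)
    cells = pd.concat([cells, compute_risks(cells)], axis=1)

    # --- district integration and correlation ---------------------------
    summary_cols = [c for c in _Y_COLUMNS_SUMMARY if c in cells.columns]
    districts = cells_to_districts(grid, cells[summary_cols],
                                   scenario.districts)
    dpop = np.zeros(len(scenario.districts))
    for j in range(len(scenario.districts)):
        dpop[j] = P[district_of == j].sum()
    districts["population"] = dpop
    districts["incidence"] = district_incidence(scenario.districts, dpop)
    r, n_used = correlate_incidence(districts["Y4"].to_numpy(),
                                    districts["incidence"].to_numpy())

    report = {
        "package_version": __version__,
        "seed": scenario.spec.seed,
        "cell_size_m": cell_size,
        "n_cells": len(grid),
        "n_districts": len(scenario.districts),
        "n_villages": len(scenario.villages),
        "params": {k: getattr(params, k)
                   for k in ModelParams.__dataclass_fields__},
        "correlation_r": r,
        "correlation_n": n_used,
        "columns": {},
    }
    for col in summary_cols:
        v = cells[col].to_numpy(float)
        report["columns"][col] = {
            "min": float(np.nanmin(v)), "mean": float(np.nanmean(v)),
            "max": float(np.nanmax(v)),
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cells.to_csv(out_dir / "cells.csv", index=False)
        districts.to_csv(out_dir / "districts.csv", index=False)
        write_geojson(grid.cells[["cell_id", "geometry"]],
                      out_dir / "cells.geojson")
        write_geojson(scenario.districts, out_dir / "districts.geojson")
        write_geojson(scenario.villages, out_dir / "villages.geojson")
        with open(out_dir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        for col in surfaces:
            surf = trend_surface(grid, cells[col].to_numpy(float),
                                 resolution=surface_resolution)
            write_ascii_grid(surf, out_dir / f"surface_{col}.asc")

    return PipelineResult(grid=grid, cells=cells, districts=districts,
                          scenario=scenario, correlation_r=r,
                          correlation_n=n_used, report=report)
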