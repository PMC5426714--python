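"""Analysis grid: construction, zonal aggregation, integration rules."""

import numpy as np
import pandas as pd
import pytest
from shapely import contains_xy
from shapely.geometry import Point, box

from anophrisk.grid import (GridSpec, build_grid, cells_to_districts,
                            itn_to_cells, landuse_proportions,
                            landuse_proportions_polygons, villages_to_cells,
                            zonal_mean)
from anophrisk.raster import Raster, minmax_normalize


def make_grid(xmax=20_000, ymax=20_000, cell=10_000):
    return build_grid(GridSpec(region=box(0, 0, xmax, ymax), cell_size=cell))


class TestBuildGrid:
    def test_single_aligned_square(self):
        g = make_grid(10_000, 10_000)
        assert len(g) == 1

    def test_25km_square_gives_nine_cells(self):
        g = make_grid(25_000, 25_000)
        assert len(g) == 9  # ceil(25/10)^2 intersecting cells

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(region=box(0, 0, 0, 0))

    def test_row_major_deterministic_ordering(self):
        a = make_grid(25_000, 25_000)
        b = make_grid(25_000, 25_000)
        assert list(a.cells["cell_id"]) == list(b.cells["cell_id"])
        rows = a.cells["row"].to_numpy()
        cols = a.cells["col"].to_numpy()
        order = np.lexsort((cols, rows))
        assert (order == np.arange(len(a))).all()

    def test_origin_snaps_to_cell_multiples(self):
        g = build_grid(GridSpec(region=box(3_000, 4_000, 18_000, 19_000),
                                cell_size=10_000))
        assert g.x_origin % 10_000 == 0 and g.y_origin % 10_000 == 0


class TestLanduseProportions:
    def test_full_coverage_single_code(self):
        g = make_grid(10_000, 10_000)
        lu = Raster(np.full((10, 10), 11), 0, 10_000, 1000)
        sp = landuse_proportions(g, lu)
        assert sp["sp_11"].iloc[0] == 1.0

    def test_half_half_exact_rectangles_polygon_path(self):
        g = make_grid(10_000, 10_000)
        layer = pd.DataFrame({
            "code": [11, 41],
            "geometry": [box(0, 0, 5_000, 10_000), box(5_000, 0, 10_000, 10_000)],
        })
        sp = landuse_proportions_polygons(g, layer)
        assert sp["sp_11"].iloc[0] == pytest.approx(0.5, abs=1e-12)
        assert sp["sp_41"].iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_raster_and_polygon_paths_agree(self):
        # same synthetic layer through both aggregation routes
        rng = np.random.default_rng(4)
        data = rng.choice([11, 41, 54], size=(20, 20))
        lu = Raster(data, 0, 10_000, 500)
        g = make_grid(10_000, 10_000, cell=5_000)
        sp_raster = landuse_proportions(g, lu)
        polys = []
        for code in (11, 41, 54):
            rows, cols = np.nonzero(data == code)
            for r, c in zip(rows, cols):
                polys.append({"code": code,
                              "geometry": box(c * 500, 10_000 - (r + 1) * 500,
                                              (c + 1) * 500, 10_000 - r * 500)})
        sp_poly = landuse_proportions_polygons(g, pd.DataFrame(polys))
        for col in sp_raster.columns:
            np.testing.assert_allclose(sp_raster[col], sp_poly[col], atol=0.01)

    def test_proportions_sum_to_one(self, default_result):
        sp_cols = [c for c in default_result.cells.columns
                   if c.startswith("sp_")]
        totals = default_result.cells[sp_cols].sum(axis=1)
        assert np.abs(totals - 1.0).max() < 1e-9


class TestZonalMean:
    def test_constant_raster(self):
        g = make_grid(20_000, 20_000)
        r = Raster(np.full((20, 20), 28.0), 0, 20_000, 1000)
        np.testing.assert_allclose(zonal_mean(g, r), 28.0)

    def test_two_value_cell(self):
        g = make_grid(10_000, 10_000)
        data = np.full((10, 10), 10.0)
        data[:, 5:] = 30.0
        r = Raster(data, 0, 10_000, 1000)
        assert zonal_mean(g, r)[0] == pytest.approx(20.0)

    def test_checkerboard(self):
        g = make_grid(10_000, 10_000)
        data = np.indices((10, 10)).sum(axis=0) % 2
        r = Raster(data.astype(float), 0, 10_000, 1000)
        assert zonal_mean(g, r)[0] == pytest.approx(0.5)

    def test_matches_per_pixel_brute_force(self):
        rng = np.random.default_rng(8)
        r = Raster(rng.uniform(0, 100, (20, 20)), 0, 20_000, 1000)
        g = make_grid(20_000, 20_000)
        production = zonal_mean(g, r)
        xc, yc = r.cell_centers()
        for i, cell in enumerate(g.cells["geometry"]):
            inside = contains_xy(cell, xc.ravel(), yc.ravel())
            assert abs(production[i] - r.data.ravel()[inside].mean()) < 1e-9

    def test_nodata_cell_missing(self):
        g = make_grid(20_000, 20_000)
        data = np.full((20, 20), 5.0)
        data[:10, :10] = np.nan  # NW cell fully missing
        r = Raster(data, 0, 20_000, 1000)
        out = zonal_mean(g, r)
        assert np.isnan(out[0]) and np.isfinite(out[1:]).all()


class TestVillages:
    def test_no_villages(self):
        g = make_grid()
        P, P_poor = villages_to_cells(g, pd.DataFrame(
            columns=["population", "poverty_fraction", "geometry"]))
        assert (P == 0).all() and (P_poor == 0).all()

    def test_population_and_poverty_integration(self):
        g = make_grid()
        v = pd.DataFrame({"population": [4000], "poverty_fraction": [0.25],
                          "geometry": [Point(2_500, 2_500)]})
        P, P_poor = villages_to_cells(g, v)
        i = P.argmax()
        assert P[i] == 4000 and P_poor[i] == 1000
        assert P.sum() == 4000

    def test_village_on_shared_edge_counted_once(self):
        g = make_grid()
        v = pd.DataFrame({"population": [100, 200],
                          "poverty_fraction": [0.0, 0.0],
                          "geometry": [Point(10_000, 5_000),     # shared edge
                                       Point(10_000, 10_000)]})  # corner
        P, _ = villages_to_cells(g, v)
        assert P.sum() == 300  # conservation: each counted exactly once


class TestItn:
    def test_district_per_capita_inherited(self):
        g = make_grid()
        districts = pd.DataFrame({"district_id": [0], "itn_count": [5000],
                                  "geometry": [box(0, 0, 20_000, 20_000)]})
        P = np.array([4000.0, 3000.0, 2000.0, 1000.0])
        D, assign = itn_to_cells(g, districts, P)
        np.testing.assert_allclose(D, 0.5)
        assert (assign == 0).all()

    def test_zero_itn(self):
        g = make_grid()
        districts = pd.DataFrame({"district_id": [0], "itn_count": [0],
                                  "geometry": [box(0, 0, 20_000, 20_000)]})
        D, _ = itn_to_cells(g, districts, np.full(len(g), 100.0))
        assert (D == 0).all()

    def test_straddling_cell_assigned_to_larger_overlap(self):
        g = make_grid()
        districts = pd.DataFrame({
            "district_id": [0, 1], "itn_count": [0, 0],
            "geometry": [box(0, 0, 4_000, 20_000),       # covers 40% of col 0
                         box(4_000, 0, 20_000, 20_000)],  # covers 60%
        })
        _, assign = itn_to_cells(g, districts, np.full(len(g), 1.0))
        assert (assign == 1).all()

    def test_zero_population_district_flagged(self):
        g = make_grid()
        districts = pd.DataFrame({"district_id": [0], "itn_count": [5000],
                                  "geometry": [box(0, 0, 20_000, 20_000)]})
        D, _ = itn_to_cells(g, districts, np.zeros(len(g)))
        assert (D == 0).all()


class TestCellsToDistricts:
    def test_constant_field(self):
        g = make_grid()
        districts = pd.DataFrame({"district_id": [0, 1],
                                  "geometry": [box(0, 0, 10_000, 20_000),
                                               box(10_000, 0, 20_000, 20_000)]})
        vals = pd.DataFrame({"v": np.full(len(g), 3.5)})
        out = cells_to_districts(g, vals, districts)
        np.testing.assert_allclose(out["v"], 3.5)

    def test_two_equal_cells(self):
        g = make_grid(20_000, 10_000)
        districts = pd.DataFrame({"district_id": [0],
                                  "geometry": [box(0, 0, 20_000, 10_000)]})
        out = cells_to_districts(g, pd.DataFrame({"v": [0.0, 1.0]}), districts)
        assert out["v"].iloc[0] == pytest.approx(0.5)

    def test_area_weighted_conservation(self):
        g = make_grid(30_000, 30_000)
        rng = np.random.default_rng(3)
        vals = pd.DataFrame({"v": rng.uniform(0, 1, len(g))})
        districts = pd.DataFrame({
            "district_id": [0, 1],
            "geometry": [box(0, 0, 13_000, 30_000),
                         box(13_000, 0, 30_000, 30_000)],
        })
        out = cells_to_districts(g, vals, districts)
        lhs = sum(out["v"].iloc[j] * districts["geometry"].iloc[j].area
                  for j in range(2))
        rhs = sum(v * g.cells["geometry"].iloc[i].area
                  for i, v in enumerate(vals["v"]))
        assert abs(lhs - rhs) / rhs < 1e-9


def test_minmax_normalize_constant_field_maps_to_half():
    out = minmax_normalize(np.full(5, 7.0))
    np.testing.assert_allclose(out, 0.5)
    v = minmax_normalize(np.array([1.0, 3.0, 2.0, np.nan]))
    assert v[0] == 0 and v[1] == 1 and np.isnan(v[3])
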