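"""Synthetic study regions for end-to-end testing of the risk pipeline.

Generates every input layer the model consumes — a patchy categorical
land-use raster, a terrain with drainage structure, smooth monthly climate
fields spanning all response regimes, clustered village points with
heterogeneous poverty, and district polygons carrying ITN allocations and
malaria case counts — all in a local projected CRS (meters) and fully
deterministic under the scenario seed.  Scenarios are structural stand-ins
for the kind of data the model runs on, not imitations of any real
geography.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .config import default_weight_table
from .raster import Raster

__all__ = ["ScenarioSpec", "Scenario", "gen_landuse", "gen_dem", "gen_climate",
           "gen_villages", "gen_districts", "generate_scenario"]


# Default monthly (lo, hi) ranges sweep a full seasonal cycle across every
# regime of the temperature and rainfall responses: months below the 15 C
# activity threshold, on the 28-33 C plateau, above the 36 C cutoff; rainfall
# months below 40 mm, near the 400 mm optimum, and beyond the 800 mm washout.
_DEFAULT_TEMP_RANGES: tuple[tuple[float, float], ...] = (
    (8, 14), (10, 16), (14, 20), (18, 26), (24, 30), (28, 33),
    (31, 35), (33, 36), (36, 40), (28, 32), (20, 28), (12, 18))
_DEFAULT_RAIN_RANGES: tuple[tuple[float, float], ...] = (
    (0, 30), (5, 50), (30, 120), (80, 250), (200, 420), (350, 650),
    (500, 850), (700, 1000), (400, 700), (150, 400), (40, 160), (0, 60))

# Default land-use mix: forest-dominated with paddy, scrub, mixed agriculture,
# wetlands, water, coffee, urban and a high-insecticide orchard class — every
# insecticide-intensity score 1-4 is represented.
_DEFAULT_LANDUSE: dict[int, float] = {
    11: 0.30, 41: 0.20, 32: 0.15, 42: 0.10, 53: 0.08,
    61: 0.05, 424: 0.07, 54: 0.03, 423: 0.02,
}


@dataclass
class ScenarioSpec:
    """Parameters of a synthetic study region.

    ``extent`` is (xmin, ymin, xmax, ymax) in projected meters;
    ``resolution_m`` the pixel size of every generated raster;
    ``landuse_codes`` maps land-use class codes to target area fractions
    (must sum to 1).  ``itn_range`` is the span of per-capita ITN densities
    across districts; village populations are log-uniform in ``pop_range``
    and below-poverty fractions uniform in ``poverty_range``.
    """

    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 120_000.0, 120_000.0)
    resolution_m: float = 1000.0
    n_districts: int = 9
    n_villages: int = 150
    landuse_codes: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_LANDUSE))
    temp_ranges: tuple[tuple[float, float], ...] = _DEFAULT_TEMP_RANGES
    rain_ranges: tuple[tuple[float, float], ...] = _DEFAULT_RAIN_RANGES
    itn_range: tuple[float, float] = (0.0, 0.6)
    pop_range: tuple[float, float] = (100.0, 8000.0)
    poverty_range: tuple[float, float] = (0.05, 0.8)
    dem_mode: str = "fractal"          # {"fractal", "plane"}
    plane_gradient: tuple[float, float] = (0.01, 0.0)  # dz/dx, dz/dy for plane mode

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("extent must have positive width and height")
        if self.resolution_m <= 0:
            raise ValueError("resolution_m must be positive")
        total = sum(self.landuse_codes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"land-use area fractions must sum to 1, got {total}")
        if len(self.temp_ranges) != 12 or len(self.rain_ranges) != 12:
            raise ValueError("need 12 monthly temperature and rainfall ranges")
        if self.n_districts < 1:
            raise ValueError("need at least one district")
        if self.dem_mode not in {"fractal", "plane"}:
            raise ValueError("dem_mode must be 'fractal' or 'plane'")
        for name in ("pop_range", "poverty_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is reversed")

    # -- derived ----------------------------------------------------------
    @property
    def raster_shape(self) -> tuple[int, int]:
        xmin, ymin, xmax, ymax = self.extent
        return (int(round((ymax - ymin) / self.resolution_m)),
                int(round((xmax - xmin) / self.resolution_m)))

    def empty_raster(self, fill: float = 0.0) -> Raster:
        nr, nc = self.raster_shape
        return Raster(np.full((nr, nc), fill), self.extent[0], self.extent[3],
                      self.resolution_m)

    def region(self):
        return box(*self.extent)

    def _rng(self, stream: str) -> np.random.Generator:
        """Independent, named random stream so layers stay decoupled.

        CRC32 of the stream name keys the stream (process-stable, unlike
        built-in str hashing), so regenerating one layer never perturbs
        another.
        """
        key = zlib.crc32(stream.encode()) % (2**31)
        ss = np.random.SeedSequence([int(self.seed), key])
        return np.random.default_rng(ss)

    # -- (de)serialisation -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed, "extent": list(self.extent),
            "resolution_m": self.resolution_m,
            "n_districts": self.n_districts, "n_villages": self.n_villages,
            "landuse_codes": {int(k): float(v)
                              for k, v in self.landuse_codes.items()},
            "temp_ranges": [list(r) for r in self.temp_ranges],
            "rain_ranges": [list(r) for r in self.rain_ranges],
            "itn_range": list(self.itn_range), "pop_range": list(self.pop_range),
            "poverty_range": list(self.poverty_range), "dem_mode": self.dem_mode,
            "plane_gradient": list(self.plane_gradient),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for key in ("extent", "itn_range", "pop_range", "poverty_range",
                    "plane_gradient"):
            if key in doc:
                doc[key] = tuple(doc[key])
        for key in ("temp_ranges", "rain_ranges"):
            if key in doc:
                doc[key] = tuple(tuple(r) for r in doc[key])
        if "landuse_codes" in doc:
            doc["landuse_codes"] = {int(k): float(v)
                                    for k, v in doc["landuse_codes"].items()}
        return cls(**doc)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise, standardised."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def gen_landuse(spec: ScenarioSpec) -> Raster:
    """Patchy categorical land-use raster hitting the target area fractions.

    A smoothed Gaussian random field is cut at its own quantiles, so realised
    fractions match the targets to within one pixel row of the sorted field
    and patches are spatially contiguous.
    """
    rng = spec._rng("landuse")
    nr, nc = spec.raster_shape
    codes = list(spec.landuse_codes)
    fracs = np.array([spec.landuse_codes[c] for c in codes])
    out = spec.empty_raster()
    if len(codes) == 1:
        out.data = np.full((nr, nc), codes[0], dtype=np.int64)
        return out
    f = _smooth_field(rng, (nr, nc), sigma=4.0)
    cuts = np.quantile(f, np.cumsum(fracs)[:-1])
    idx = np.searchsorted(cuts, f, side="right")
    out.data = np.asarray(codes, dtype=np.int64)[idx]
    return out


def gen_dem(spec: ScenarioSpec) -> Raster:
    """Elevation raster (m): multi-scale fractal surface or inclined plane.

    The fractal mode superposes smoothed noise octaves on a gentle regional
    tilt so at least one drainage outlet sits on the boundary; the plane mode
    is a deterministic inclined plane for routing oracles.
    """
    nr, nc = spec.raster_shape
    out = spec.empty_raster()
    xc, yc = out.cell_centers()
    if spec.dem_mode == "plane":
        gx, gy = spec.plane_gradient
        out.data = 500.0 + gx * (xc - spec.extent[0]) + gy * (yc - spec.extent[1])
        return out
    rng = spec._rng("dem")
    z = np.zeros((nr, nc))
    for sigma, amp in ((16, 300.0), (8, 120.0), (4, 50.0), (2, 15.0)):
        z += amp * _smooth_field(rng, (nr, nc), sigma)
    # regional tilt toward the western boundary: guarantees a boundary outlet
    z += 0.002 * (xc - spec.extent[0])
    z -= z.min()
    out.data = z + 100.0
    return out


def gen_climate(spec: ScenarioSpec) -> tuple[list[Raster], list[Raster]]:
    """12 monthly mean-temperature (deg C) and rainfall (mm/month) rasters.

    Each month is a smooth surface (north-south gradient plus low-frequency
    noise) min-max rescaled exactly onto that month's configured range.
    """
    rng = spec._rng("climate")
    nr, nc = spec.raster_shape
    grad = np.linspace(1.0, 0.0, nr)[:, None] * np.ones((1, nc))  # warm south

    def rescale(f, lo, hi):
        fmin, fmax = f.min(), f.max()
        if hi == lo or fmax == fmin:
            return np.full((nr, nc), float(lo))
        return lo + (f - fmin) / (fmax - fmin) * (hi - lo)

    def max_jump(d):
        j = 0.0
        if d.shape[0] > 1:
            j = max(j, np.abs(np.diff(d, axis=0)).max())
        if d.shape[1] > 1:
            j = max(j, np.abs(np.diff(d, axis=1)).max())
        return j

    def fields(ranges):
        out = []
        for lo, hi in ranges:
            f = grad + 0.6 * _smooth_field(rng, (nr, nc), sigma=8.0)
            data = rescale(f, lo, hi)
            # smoothness contract: no pixel-to-pixel jump beyond 5% of range
            while hi > lo and max_jump(data) > 0.05 * (hi - lo):
                f = ndimage.gaussian_filter(f, 1.5, mode="nearest")
                data = rescale(f, lo, hi)
            r = spec.empty_raster()
            r.data = data
            out.append(r)
        return out

    return fields(spec.temp_ranges), fields(spec.rain_ranges)


def gen_villages(spec: ScenarioSpec) -> pd.DataFrame:
    """Clustered village points with population and below-poverty fraction.

    Villages scatter (Gaussian, 4 km s.d.) around a handful of cluster
    centers, mimicking the strongly aggregated settlement pattern of rural
    village lists; populations are log-uniform in ``pop_range``.
    """
    rng = spec._rng("villages")
    xmin, ymin, xmax, ymax = spec.extent
    n = spec.n_villages
    if n == 0:
        return pd.DataFrame(columns=["population", "poverty_fraction", "geometry"])
    n_centers = max(1, n // 25)
    cx = rng.uniform(xmin + 0.05 * (xmax - xmin), xmax - 0.05 * (xmax - xmin),
                     n_centers)
    cy = rng.uniform(ymin + 0.05 * (ymax - ymin), ymax - 0.05 * (ymax - ymin),
                     n_centers)
    which = rng.integers(0, n_centers, n)
    x = np.clip(cx[which] + rng.normal(0, 4000, n), xmin, np.nextafter(xmax, xmin))
    y = np.clip(cy[which] + rng.normal(0, 4000, n), ymin, np.nextafter(ymax, ymin))
    lo, hi = spec.pop_range
    pop = np.exp(rng.uniform(np.log(max(lo, 1.0)), np.log(max(hi, 1.0)), n))
    pov = rng.uniform(*spec.poverty_range, n) if spec.poverty_range[1] > \
        spec.poverty_range[0] else np.full(n, spec.poverty_range[0])
    return pd.DataFrame({
        "population": np.round(pop).astype(int),
        "poverty_fraction": pov,
        "geometry": [Point(xi, yi) for xi, yi in zip(x, y)],
    })


def gen_districts(spec: ScenarioSpec,
                  villages: pd.DataFrame | None = None) -> pd.DataFrame:
    """District polygons partitioning the extent, with ITN and case counts.

    Districts are Voronoi cells of random seed points clipped to the extent
    (a gap- and overlap-free partition).  Per-capita ITN targets are spread
    evenly across ``itn_range`` and converted to net counts with the
    district's village population; malaria cases are Poisson draws whose
    rate follows the district's true environmental hazard in this synthetic
    world — mean land-use suitability weighted by terrain wetness — so
    incidence carries an environmental gradient the pipeline can recover.
    """
    rng = spec._rng("districts")
    region = spec.region()
    k = spec.n_districts
    if k == 1:
        polys = [region]
    else:
        xmin, ymin, xmax, ymax = spec.extent
        pts = MultiPoint([Point(rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
                          for _ in range(k)])
        cells = voronoi_diagram(pts, envelope=region)
        # voronoi output order is unspecified: re-order by seed point
        polys = [None] * k
        for geom in cells.geoms:
            for i, p in enumerate(pts.geoms):
                if polys[i] is None and geom.contains(p):
                    polys[i] = geom.intersection(region)
                    break
        polys = [p for p in polys if p is not None]

    if villages is None:
        villages = gen_villages(spec)
    pops = np.zeros(len(polys))
    if len(villages):
        from shapely.strtree import STRtree
        tree = STRtree(list(villages["geometry"]))
        for i, poly in enumerate(polys):
            idx = tree.query(poly, predicate="intersects")
            pops[i] = villages["population"].iloc[idx].sum()

    percap = np.linspace(*spec.itn_range, len(polys))
    rng.shuffle(percap)
    itn = np.round(percap * pops).astype(int)

    # true environmental hazard of the synthetic world: land-use suitability
    # weighted by terrain wetness; the district case rate follows it
    from .terrain import compute_terrain
    wt = default_weight_table()
    lu = gen_landuse(spec)
    wet = compute_terrain(gen_dem(spec)).twi_norm.data
    xc, yc = lu.cell_centers()
    a_mean = np.vectorize(lambda c: np.mean(
        [wt.suitability(c, s) for s in ("dirus", "maculatus", "minimus")]))
    hazard = (a_mean(lu.data) / 10.0) * wet
    rates = np.zeros(len(polys))
    from shapely import contains_xy
    for i, poly in enumerate(polys):
        inside = contains_xy(poly, xc.ravel(), yc.ravel())
        rates[i] = hazard.ravel()[inside].mean() if inside.any() else 0.0
    # spread rates over the realised hazard span so the synthetic world has a
    # clear environment-to-incidence gradient across districts
    if np.ptp(rates) > 0:
        rates = (rates - rates.min()) / np.ptp(rates)
    base = 0.002 + 0.03 * rates  # cases per person-year
    cases = rng.poisson(base * pops)

    return pd.DataFrame({
        "district_id": np.arange(len(polys)),
        "itn_count": itn,
        "malaria_cases": cases,
        "population_tested": np.round(pops).astype(int),
        "geometry": polys,
    })


@dataclass
class Scenario:
    """A complete synthetic study region (all model input layers)."""

    spec: ScenarioSpec
    landuse: Raster
    dem: Raster
    temperature: list[Raster]
    rainfall: list[Raster]
    villages: pd.DataFrame
    districts: pd.DataFrame


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Generate every input layer of a scenario, deterministically."""
    villages = gen_villages(spec)
    temp, rain = gen_climate(spec)
    return Scenario(
        spec=spec,
        landuse=gen_landuse(spec),
        dem=gen_dem(spec),
        temperature=temp,
        rainfall=rain,
        villages=villages,
        districts=gen_districts(spec, villages=villages),
    )
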