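"""Lightweight gridded-raster container with plain-text (ESRI ASCII grid) I/O.

All rasters in this package live in a projected, metric CRS with square
pixels and north-up orientation: row 0 is the northernmost row.  The ESRI
ASCII grid format keeps the deliverables human-readable and diffable while
carrying the georeferencing (lower-left corner + cell size) every module
needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid", "minmax_normalize"]


@dataclass
class Raster:
    """A single-band, north-up, square-pixel raster in projected meters.

    Parameters
    ----------
    data : ndarray, shape (nrows, ncols)
        Cell values; row 0 is the northern edge.
    x0, y0 : float
        Coordinates of the *top-left corner* of the top-left pixel (m).
    dx : float
        Pixel size in meters (square pixels).
    nodata : float or None
        Sentinel for missing cells; NaN is also honoured for float data.
    """

    data: np.ndarray
    x0: float
    y0: float
    dx: float
    nodata: float | None = None
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.dx <= 0:
            raise ValueError("pixel size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent."""
        nr, nc = self.data.shape
        return (self.x0, self.y0 - nr * self.dx, self.x0 + nc * self.dx, self.y0)

    @property
    def pixel_area(self) -> float:
        return self.dx * self.dx

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xc, yc) of pixel-center coordinates, shape = raster shape."""
        nr, nc = self.data.shape
        xc = self.x0 + (np.arange(nc) + 0.5) * self.dx
        yc = self.y0 - (np.arange(nr) + 0.5) * self.dx
        return np.meshgrid(xc, yc)

    # -- masking ----------------------------------------------------------
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of pixels carrying data."""
        m = np.ones(self.data.shape, dtype=bool)
        if self.nodata is not None:
            m &= self.data != self.nodata
        if np.issubdtype(self.data.dtype, np.floating):
            m &= ~np.isnan(self.data)
        return m

    def values_masked(self) -> np.ndarray:
        """Float copy with missing pixels set to NaN."""
        out = self.data.astype(float, copy=True)
        out[~self.valid_mask()] = np.nan
        return out

    def copy_with(self, data: np.ndarray, nodata: float | None = None) -> "Raster":
        return Raster(data, self.x0, self.y0, self.dx, nodata=nodata, crs=self.crs)


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.8g") -> None:
    """Write a raster as an ESRI ASCII grid (text)."""
    path = Path(path)
    nr, nc = raster.shape
    nodata = raster.nodata if raster.nodata is not None else -9999.0
    data = raster.data.astype(float, copy=True)
    data[~raster.valid_mask()] = nodata
    yll = raster.y0 - nr * raster.dx
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {raster.x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {raster.dx!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any GIS)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        data = np.loadtxt(fh)
    nr, nc = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nr, nc)
    dx = header["cellsize"]
    y0 = header["yllcorner"] + nr * dx
    return Raster(data, header["xllcorner"], y0, dx,
                  nodata=header.get("nodata_value"))


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1] over finite entries; a constant field maps to 0.5.

    NaNs are propagated.  Used to place the topographic wetness index on the
    [0, 1] scale before it modulates the rainfall and insecticide scores.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        return np.full_like(v, np.nan)
    lo = v[finite].min()
    hi = v[finite].max()
    out = np.full_like(v, np.nan)
    if hi == lo:
        out[finite] = 0.5
    else:
        out[finite] = (v[finite] - lo) / (hi - lo)
    return out
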