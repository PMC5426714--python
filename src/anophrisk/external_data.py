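"""Loading a real study database (optional reproduction mode).

The pipeline can run on real national data instead of a synthetic scenario.
This loader expects a directory of open-format layers (converted from the
source GIS database with any standard tool):

* ``landuse.asc``      — categorical land-use raster, class codes matching
  the shipped weight table;
* ``dem.asc``          — elevation raster (m);
* ``temp_01.asc`` .. ``temp_12.asc`` — monthly mean temperature (deg C);
* ``rain_01.asc`` .. ``rain_12.asc`` — monthly rainfall (mm);
* ``villages.geojson`` — Point features with ``population`` and
  ``poverty_fraction``;
* ``districts.geojson`` — Polygon features with ``district_id``,
  ``itn_count``, ``malaria_cases``, ``population_tested``;
* ``region.geojson``   — single boundary polygon.

All layers must share one projected, metric CRS.  The loader returns a
:class:`~anophrisk.synth.Scenario`-shaped bundle that
:func:`~anophrisk.pipeline.run_pipeline` accepts directly.
"""

from __future__ import annotations

from pathlib import Path

from shapely.geometry import Polygon

from .geoio import read_geojson
from .raster import read_ascii_grid
from .synth import Scenario, ScenarioSpec

__all__ = ["load_study_inputs"]

_RASTER_LAYERS = ["landuse.asc", "dem.asc"] + \
    [f"temp_{m:02d}.asc" for m in range(1, 13)] + \
    [f"rain_{m:02d}.asc" for m in range(1, 13)]
_VECTOR_LAYERS = ["villages.geojson", "districts.geojson", "region.geojson"]


def load_study_inputs(directory: str | Path) -> tuple[Scenario, Polygon]:
    """Load real input layers for a pipeline run.

    Raises ``FileNotFoundError`` naming the first missing layer, so a
    partially converted database fails loudly rather than silently running
    on a subset.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(
            f"study-input directory {directory} does not exist; expected a "
            f"directory containing {', '.join(_RASTER_LAYERS[:2] + _VECTOR_LAYERS)} "
            "and the 24 monthly climate rasters")
    for name in _RASTER_LAYERS + _VECTOR_LAYERS:
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing input layer: {directory / name}")

    landuse = read_ascii_grid(directory / "landuse.asc")
    dem = read_ascii_grid(directory / "dem.asc")
    temp = [read_ascii_grid(directory / f"temp_{m:02d}.asc")
            for m in range(1, 13)]
    rain = [read_ascii_grid(directory / f"rain_{m:02d}.asc")
            for m in range(1, 13)]
    villages = read_geojson(directory / "villages.geojson")
    districts = read_geojson(directory / "districts.geojson")
    region_tbl = read_geojson(directory / "region.geojson")
    region = region_tbl["geometry"].iloc[0]

    xmin, ymin, xmax, ymax = region.bounds
    spec = ScenarioSpec(seed=0, extent=(xmin, ymin, xmax, ymax),
                        resolution_m=dem.dx)
    scenario = Scenario(spec=spec, landuse=landuse, dem=dem, temperature=temp,
                        rainfall=rain, villages=villages, districts=districts)
    return scenario, region
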