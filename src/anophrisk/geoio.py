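"""GeoJSON I/O for the package's vector layers.

Vector layers travel as pandas DataFrames carrying a ``geometry`` column of
shapely objects (a deliberately small subset of the geopandas convention):
villages are Point features with ``population`` and ``poverty_fraction``;
districts are Polygon features with ``district_id``, ``itn_count``,
``malaria_cases`` and ``population_tested``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

__all__ = ["write_geojson", "read_geojson"]


def write_geojson(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame with a shapely ``geometry`` column as GeoJSON."""
    if "geometry" not in table.columns:
        raise ValueError("table has no 'geometry' column")
    features = []
    props_cols = [c for c in table.columns if c != "geometry"]
    for _, row in table.iterrows():
        props = {}
        for c in props_cols:
            v = row[c]
            if hasattr(v, "item"):  # numpy scalar -> plain python
                v = v.item()
            props[c] = v
        features.append({
            "type": "Feature",
            "geometry": mapping(row["geometry"]),
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path: str | Path) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection into a DataFrame (+geometry column)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    rows = []
    for feat in doc["features"]:
        row = dict(feat.get("properties") or {})
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    return pd.DataFrame(rows)
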