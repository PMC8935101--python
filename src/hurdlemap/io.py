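"""Reading and writing the on-disk formats: GeoJSON geometry, CSV tables.

Geometry travels as RFC 7946 GeoJSON FeatureCollections (one feature per
tract, ``tract_id`` plus any tabular columns as properties), built with
shapely's geo-interface mapping. Coordinates are expected to be projected,
metre-based — no CRS handling is performed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape


def write_geojson(table: pd.DataFrame, geometry: list, path) -> None:
    """Write one feature per table row with the row's columns as properties."""
    if len(table) != len(geometry):
        raise ValueError("table and geometry lengths differ")
    features = []
    for (tract_id, row), geom in zip(table.iterrows(), geometry):
        props = {"tract_id": _py(tract_id)}
        props.update({k: _py(v) for k, v in row.items()})
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))


def read_geojson(path):
    """Read a FeatureCollection back into (table indexed by tract_id, geometry list)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
    rows, geoms = [], []
    for feat in doc["features"]:
        rows.append(dict(feat["properties"]))
        geoms.append(shape(feat["geometry"]))
    table = pd.DataFrame(rows)
    if "tract_id" not in table.columns:
        raise ValueError("features lack a tract_id property")
    table = table.set_index("tract_id")
    return table, geoms


def _py(v):
    try:
        if float(v) == int(v):
            return int(v)
        return float(v)
    except (TypeError, ValueError):
        return v
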