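"""Readers, writers and schema validators for the pipeline's file formats.

Formats are deliberately plain: CSV for locations, bearings, fixes and
distance tables; GeoJSON (planar coordinates in meters, CRS declared in the
file's top-level properties) for feature layers and home ranges; JSON for run
configuration and reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, mapping, shape

from .homerange import HomeRange
from .landscape import FeatureLayer, LocationSet

__all__ = [
    "SchemaError",
    "write_feature_layer",
    "read_feature_layer",
    "write_locations",
    "read_locations",
    "write_report",
]

LOCATION_ROLES = {"homerange_centroid", "homerange_contour", "lek", "nest", "random"}


class SchemaError(ValueError):
    """An input file violates the expected schema."""


def write_feature_layer(layer: FeatureLayer, path) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": {"index": i}}
        for i, g in enumerate(layer.geometries)
    ]
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "name": layer.name,
            "kind": layer.kind,
            "crs_note": "planar projected coordinates, meters",
        },
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_feature_layer(path) -> FeatureLayer:
    doc = json.loads(Path(path).read_text())
    props = doc.get("properties", {})
    name = props.get("name", Path(path).stem)
    kind = props.get("kind")
    geoms = []
    for i, feat in enumerate(doc.get("features", [])):
        g = shape(feat["geometry"])
        if kind == "point" and not isinstance(g, Point):
            raise SchemaError(f"feature {i} in point layer {name!r} is {g.geom_type}")
        if kind == "line" and not isinstance(g, LineString):
            raise SchemaError(f"feature {i} in line layer {name!r} is {g.geom_type}")
        geoms.append(g)
    if kind is None:
        kind = "point" if geoms and isinstance(geoms[0], Point) else "line"
    return FeatureLayer(name=name, kind=kind, geometries=geoms)


def write_locations(locations: LocationSet, path) -> None:
    pd.DataFrame(
        {"id": locations.ids, "role": locations.role, "x_m": locations.x, "y_m": locations.y}
    ).to_csv(path, index=False)


def read_locations(path) -> list[LocationSet]:
    """Read a locations CSV (columns id, role, x_m, y_m) into per-role sets."""
    df = pd.read_csv(path)
    missing = {"id", "role", "x_m", "y_m"} - set(df.columns)
    if missing:
        raise SchemaError(f"locations file missing column(s): {', '.join(sorted(missing))}")
    if not np.all(np.isfinite(df[["x_m", "y_m"]].to_numpy())):
        bad = df.index[~np.isfinite(df[["x_m", "y_m"]]).all(axis=1)].tolist()
        raise SchemaError(f"non-finite coordinates at row(s) {bad[:10]}")
    unknown = set(df["role"].unique()) - LOCATION_ROLES
    if unknown:
        raise SchemaError(f"unknown role(s): {', '.join(sorted(map(str, unknown)))}")
    out = []
    for role, grp in df.groupby("role", sort=True):
        out.append(
            LocationSet(
                x=grp["x_m"].to_numpy(),
                y=grp["y_m"].to_numpy(),
                role=str(role),
                ids=grp["id"].to_numpy(),
            )
        )
    return out


def read_bearings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"animal_id", "timestamp", "station_x_m", "station_y_m", "azimuth_deg"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"bearings file missing column(s): {', '.join(sorted(missing))}")
    return df


def write_home_ranges(home_ranges: list[HomeRange], path) -> None:
    features = []
    for hr in home_ranges:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(hr.contour),
                "properties": {
                    "animal_id": hr.animal_id,
                    "year": hr.year,
                    "centroid_x_m": hr.centroid[0],
                    "centroid_y_m": hr.centroid[1],
                    "isopleth": hr.isopleth,
                    "area_m2": hr.area_m2,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "properties": {"crs_note": "planar projected coordinates, meters"},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2))
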