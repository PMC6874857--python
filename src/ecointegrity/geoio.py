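"""Plain-text geospatial I/O: ESRI ASCII grids and GeoJSON feature collections.

Rasters are exchanged as single-band ESRI ASCII grids (``.asc``), a
text format readable by every desktop GIS.  Vector features travel as
GeoJSON with ``threat`` / ``category`` / ``attribute`` properties.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from .grids import GridSpec

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_feature_collection",
    "read_feature_collection",
]

NODATA = -9999.0


def write_ascii_grid(path, grid: GridSpec, values: np.ndarray) -> None:
    """Write ``values`` (row 0 = south) as an ESRI ASCII grid."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"array shape {values.shape} != grid shape {grid.shape}")
    out = np.where(np.isfinite(values), values, NODATA)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y!r}\n"
        f"cellsize {grid.pixel_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI ASCII stores the northern row first
        for row in out[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; returns (GridSpec, values with row 0 = south)."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = GridSpec(
            origin_x=header["xllcorner"],
            origin_y=header["yllcorner"],
            pixel_size=header["cellsize"],
            ncols=int(header["ncols"]),
            nrows=int(header["nrows"]),
        )
        values = np.loadtxt(fh).reshape(grid.shape)
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return grid, values[::-1]


def write_feature_collection(path, features) -> None:
    """Write ThreatFeature-like records to a GeoJSON FeatureCollection."""
    out = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": {
                    "threat": f.threat,
                    "category": f.category,
                    "attribute": f.attribute,
                },
            }
            for f in features
        ],
    }
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True))


def read_feature_collection(path):
    """Read a GeoJSON FeatureCollection into ThreatFeature records."""
    from .threats import ThreatFeature  # local import: avoid cycle

    raw = json.loads(Path(path).read_text())
    feats = []
    for item in raw["features"]:
        props = item.get("properties") or {}
        geom = shape(item["geometry"])
        if geom.is_empty or not shapely.is_valid(geom):
            raise ValueError(f"invalid or empty geometry in {path}")
        feats.append(
            ThreatFeature(
                geometry=geom,
                threat=props["threat"],
                category=props["category"],
                attribute=props.get("attribute"),
            )
        )
    return feats


def write_polygon_collection(path, ids, polygons) -> None:
    """Write microbasin polygons with an ``id`` property."""
    out = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {"id": pid},
            }
            for pid, poly in zip(ids, polygons, strict=True)
        ],
    }
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True))


def read_polygon_collection(path):
    """Read polygons with an ``id`` property; returns (ids, polygons)."""
    raw = json.loads(Path(path).read_text())
    ids, polys = [], []
    for item in raw["features"]:
        ids.append((item.get("properties") or {})["id"])
        polys.append(shape(item["geometry"]))
    return ids, polys
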