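"""Spherical-geometry helpers and GeoJSON I/O.

All layers use unprojected WGS84 longitude/latitude coordinates
(longitude in (-180, 180]). Areas are evaluated on the authalic sphere —
the sphere with the same surface area as the WGS84 ellipsoid — and
reported in hectares; distances are great-circle.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

#: WGS84 authalic radius, metres.
EARTH_RADIUS_M = 6_371_007.181


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres (array-broadcasting)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def _ring_area_m2(coords: np.ndarray) -> float:
    """Signed spherical area of a closed lon/lat ring (Chamberlain-Duquette)."""
    lon = np.radians(coords[:, 0])
    lat = np.radians(coords[:, 1])
    lon2, lat2 = np.roll(lon, -1), np.roll(lat, -1)
    area = np.sum((lon2 - lon) * (2 + np.sin(lat) + np.sin(lat2)))
    return float(area * EARTH_RADIUS_M**2 / 2.0)


def spherical_area_m2(geom: BaseGeometry) -> float:
    """Unsigned area of a (multi)polygon on the authalic sphere, m^2."""
    if geom.is_empty:
        return 0.0
    gt = geom.geom_type
    if gt == "Polygon":
        area = abs(_ring_area_m2(np.asarray(geom.exterior.coords)))
        for ring in geom.interiors:
            area -= abs(_ring_area_m2(np.asarray(ring.coords)))
        return area
    if gt in ("MultiPolygon", "GeometryCollection"):
        return sum(
            spherical_area_m2(g) for g in geom.geoms if g.geom_type.endswith("Polygon")
        )
    return 0.0


def spherical_area_ha(geom: BaseGeometry) -> float:
    """Unsigned (multi)polygon area in hectares."""
    return spherical_area_m2(geom) / 10_000.0


class LocalMetricFrame:
    """Equirectangular metre frame around a reference latitude/longitude.

    Adequate for metre-scale buffering of coastal features over domains of
    a few degrees; not for basin-scale geometry.
    """

    def __init__(self, lat0: float, lon0: float):
        self.lat0, self.lon0 = float(lat0), float(lon0)
        self._mx = EARTH_RADIUS_M * np.cos(np.radians(lat0)) * np.pi / 180.0
        self._my = EARTH_RADIUS_M * np.pi / 180.0

    @classmethod
    def around(cls, geom: BaseGeometry) -> "LocalMetricFrame":
        c = geom.centroid
        return cls(c.y, c.x)

    def to_metres(self, geom: BaseGeometry) -> BaseGeometry:
        from shapely.ops import transform

        return transform(
            lambda x, y: ((np.asarray(x) - self.lon0) * self._mx, (np.asarray(y) - self.lat0) * self._my),
            geom,
        )

    def to_degrees(self, geom: BaseGeometry) -> BaseGeometry:
        from shapely.ops import transform

        return transform(
            lambda x, y: (np.asarray(x) / self._mx + self.lon0, np.asarray(y) / self._my + self.lat0),
            geom,
        )


def buffer_metres(geom: BaseGeometry, metres: float) -> BaseGeometry:
    """Buffer a lon/lat geometry by a metric distance via a local frame."""
    frame = LocalMetricFrame.around(geom)
    return frame.to_degrees(frame.to_metres(geom).buffer(metres))


def read_geojson(path: str | Path) -> list[dict]:
    """Read a GeoJSON FeatureCollection into records with shapely geometry."""
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    out = []
    for feat in fc["features"]:
        rec = dict(feat.get("properties") or {})
        rec["geometry"] = shape(feat["geometry"])
        out.append(rec)
    return out


def write_geojson(records: list[dict], path: str | Path) -> None:
    """Write records (dicts with a shapely ``geometry`` key) as GeoJSON."""
    feats = []
    for rec in records:
        props = {k: v for k, v in rec.items() if k != "geometry"}
        feats.append(
            {"type": "Feature", "properties": props, "geometry": mapping(rec["geometry"])}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )
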