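"""Local metric geometry for route-based linear referencing.

All coordinates are stored in WGS84 (lon/lat degrees). Every metric
computation — route length, chainage, snapping distances, cluster gaps — runs
in a local east/north tangent frame centred on the route. Over a city-scale
route (a few km) an ellipsoidal equirectangular projection, using the WGS84
radii of curvature at the reference latitude, is accurate to well below 0.1%,
which is far tighter than any threshold used in the analysis (snap tolerances
and cluster gaps are tens of metres).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from shapely.geometry import LineString, Point

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)


@dataclass(frozen=True)
class LocalProjection:
    """East/north metric frame tangent to the WGS84 ellipsoid at (lat0, lon0)."""

    lat0: float
    lon0: float

    @property
    def _radii(self) -> tuple[float, float]:
        s2 = math.sin(math.radians(self.lat0)) ** 2
        w = math.sqrt(1.0 - WGS84_E2 * s2)
        n = WGS84_A / w                       # prime vertical radius
        m = WGS84_A * (1.0 - WGS84_E2) / w**3  # meridional radius
        return m, n

    def forward(self, lon, lat):
        """Degrees -> metres (east, north). Accepts scalars or arrays."""
        m, n = self._radii
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = np.radians(lon - self.lon0) * n * math.cos(math.radians(self.lat0))
        y = np.radians(lat - self.lat0) * m
        return x, y

    def inverse(self, x, y):
        """Metres (east, north) -> degrees (lon, lat)."""
        m, n = self._radii
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = self.lon0 + np.degrees(x / (n * math.cos(math.radians(self.lat0))))
        lat = self.lat0 + np.degrees(y / m)
        return lon, lat


def projection_for(lons, lats) -> LocalProjection:
    """Projection centred on the centroid of the given WGS84 coordinates."""
    return LocalProjection(float(np.mean(lats)), float(np.mean(lons)))


def projected_linestring(lons, lats, proj: LocalProjection) -> LineString:
    x, y = proj.forward(np.asarray(lons), np.asarray(lats))
    return LineString(np.column_stack([x, y]))


def chainage_and_offset(line_m: LineString, proj: LocalProjection, lon, lat):
    """Snap one WGS84 point to a projected polyline.

    Returns ``(chainage_m, offset_m)``: distance along the line of the nearest
    point, and the perpendicular snap distance.
    """
    x, y = proj.forward(lon, lat)
    p = Point(float(x), float(y))
    return float(line_m.project(p)), float(line_m.distance(p))


def point_at_chainage(line_m: LineString, proj: LocalProjection, chainage: float):
    """WGS84 (lon, lat) of the route point at the given chainage [m]."""
    p = line_m.interpolate(chainage)
    lon, lat = proj.inverse(p.x, p.y)
    return float(lon), float(lat)
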