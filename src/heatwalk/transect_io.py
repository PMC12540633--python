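"""Reading, validating and organising mobile transect data.

A measurement campaign is a set of *laps*: one lap is a single traversal of
the monitoring route with a handheld device logging one record per second
(GNSS timestamp and position plus six meteorological channels). Laps are
grouped into four daily *sessions* by planned start time (06:00, 12:00,
15:30, 20:00); session membership is campaign metadata, never inferred from
the clock. Parsing is total: every input row becomes either a record or an
entry in the quality-control report.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
from lxml import etree
from shapely.geometry import LineString, mapping

from .geo import LocalProjection, projected_linestring, projection_for

logger = logging.getLogger(__name__)

__all__ = [
    "MetRecord",
    "Session",
    "Lap",
    "Campaign",
    "Route",
    "RowIssue",
    "ParseResult",
    "DEFAULT_COLUMN_MAP",
    "read_device_log",
    "assemble_campaign",
    "read_route",
    "write_geojson",
    "read_geojson_features",
]


class ConfigurationError(ValueError):
    """A problem with user-supplied configuration (column maps, thresholds)."""


@dataclass(frozen=True)
class MetRecord:
    """One 1-Hz observation from the handheld device."""

    timestamp: dt.datetime
    lat: float
    lon: float
    air_temp: float        # degC
    rel_humidity: float    # %
    pressure: float        # hPa
    surface_temp: float    # degC
    globe_temp: float      # degC
    global_irradiance: float  # W/m2


#: canonical field -> (min, max) physical plausibility bounds
_RANGES = {
    "lat": (-90.0, 90.0),
    "lon": (-180.0, 180.0),
    "rel_humidity": (0.0, 100.0),
    "pressure": (800.0, 1100.0),
    "air_temp": (-60.0, 70.0),
    "surface_temp": (-60.0, 90.0),
    "globe_temp": (-60.0, 90.0),
    "global_irradiance": (0.0, 1500.0),
}

DEFAULT_COLUMN_MAP = {
    "timestamp": "timestamp",
    "lat": "lat",
    "lon": "lon",
    "air_temp": "air_temp_c",
    "rel_humidity": "rh_pct",
    "pressure": "pressure_hpa",
    "surface_temp": "surface_temp_c",
    "globe_temp": "globe_temp_c",
    "global_irradiance": "irradiance_wm2",
}


@dataclass(frozen=True)
class RowIssue:
    line: int
    field: str
    message: str


@dataclass
class ParseResult:
    records: list[MetRecord]
    issues: list[RowIssue]
    n_rows: int

    @property
    def failure_fraction(self) -> float:
        bad = self.n_rows - len(self.records)
        return bad / self.n_rows if self.n_rows else 0.0


def _parse_timestamp(text: str) -> dt.datetime:
    ts = dt.datetime.fromisoformat(text.strip().replace("Z", "+00:00"))
    if ts.tzinfo is not None:
        ts = ts.astimezone(dt.timezone.utc).replace(tzinfo=None)
    return ts


def read_device_log(
    source: str | Path | IO[str],
    column_map: dict[str, str] | None = None,
) -> ParseResult:
    """Parse a device CSV log into validated records plus a QC report.

    ``column_map`` maps canonical field names (keys of
    :data:`DEFAULT_COLUMN_MAP`) to the column names present in the file, so
    arbitrary column order and localised headers are supported. Rows failing
    type or range checks are excluded from ``records`` and listed as
    :class:`RowIssue` items — never silently dropped.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMN_MAP)
        if unknown:
            raise ConfigurationError(f"unknown canonical fields in column_map: {sorted(unknown)}")
        cmap.update(column_map)

    close = False
    if isinstance(source, (str, Path)):
        fh: IO[str] = open(source, "r", newline="")
        close = True
    else:
        fh = source
    try:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ConfigurationError("device log has no header row")
        missing = [v for v in cmap.values() if v not in reader.fieldnames]
        if missing:
            raise ConfigurationError(f"mapped columns absent from header: {missing}")

        records: list[MetRecord] = []
        issues: list[RowIssue] = []
        n_rows = 0
        for line_no, row in enumerate(reader, start=2):  # header is line 1
            n_rows += 1
            try:
                ts = _parse_timestamp(row[cmap["timestamp"]])
            except (ValueError, TypeError):
                issues.append(RowIssue(line_no, "timestamp",
                                       f"unparseable timestamp {row[cmap['timestamp']]!r}"))
                continue
            values: dict[str, float] = {}
            bad = False
            for fld in ("lat", "lon", "air_temp", "rel_humidity", "pressure",
                        "surface_temp", "globe_temp", "global_irradiance"):
                raw = row[cmap[fld]]
                try:
                    val = float(raw)
                except (ValueError, TypeError):
                    issues.append(RowIssue(line_no, fld, f"not a number: {raw!r}"))
                    bad = True
                    break
                lo, hi = _RANGES[fld]
                if not (lo <= val <= hi) or not math.isfinite(val):
                    issues.append(RowIssue(line_no, fld, f"out of range [{lo}, {hi}]: {val}"))
                    bad = True
                    break
                values[fld] = val
            if bad:
                continue
            records.append(MetRecord(timestamp=ts, **values))
        return ParseResult(records=records, issues=issues, n_rows=n_rows)
    finally:
        if close:
            fh.close()


class Session(Enum):
    """Daily measurement session, labelled by planned start time."""

    MORNING = "06:00"
    MIDDAY = "12:00"
    AFTERNOON = "15:30"
    EVENING = "20:00"

    @property
    def nominal_start_hour(self) -> float:
        h, m = self.value.split(":")
        return int(h) + int(m) / 60.0

    @classmethod
    def order(cls) -> list["Session"]:
        return [cls.MORNING, cls.MIDDAY, cls.AFTERNOON, cls.EVENING]


@dataclass
class Lap:
    """One traversal of the route: an ordered 1-Hz record sequence."""

    lap_id: str
    date: dt.date
    session: Session
    lap_index: int  # 1 or 2
    records: list[MetRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lap_index not in (1, 2):
            raise ValueError(f"lap_index must be 1 or 2, got {self.lap_index}")
        ts = [r.timestamp for r in self.records]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"lap {self.lap_id}: timestamps not strictly increasing")

    @property
    def key(self) -> tuple[dt.date, Session, int]:
        return (self.date, self.session, self.lap_index)

    @property
    def duration_s(self) -> float:
        if len(self.records) < 2:
            return 0.0
        return (self.records[-1].timestamp - self.records[0].timestamp).total_seconds()

    def check_duration(self, window_s: tuple[float, float] = (20 * 60, 60 * 60)) -> bool:
        """True if the lap duration lies in the plausibility window (default 20-60 min)."""
        lo, hi = window_s
        return lo <= self.duration_s <= hi


@dataclass
class Campaign:
    """All retained laps of a measurement campaign plus exclusion bookkeeping."""

    laps: list[Lap]
    excluded: list[tuple[dt.date, Session, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [lap.key for lap in self.laps]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (date, session, lap_index) among laps")
        self.laps.sort(key=lambda lap: (lap.date, lap.session.nominal_start_hour, lap.lap_index))

    @property
    def n_laps(self) -> int:
        return len(self.laps)

    def session_laps(self, session: Session) -> list[Lap]:
        return [lap for lap in self.laps if lap.session is session]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Campaign):
            return NotImplemented
        return self.laps == other.laps and sorted(self.excluded) == sorted(other.excluded)


def assemble_campaign(
    laps: Iterable[Lap],
    exclusions: Sequence[tuple[dt.date, Session, int, str]] = (),
) -> Campaign:
    """Build a campaign, removing exactly the listed laps.

    Exclusions are ``(date, session, lap_index, reason)`` tuples (the field
    protocol's "unsuitable weather" bookkeeping). Referencing a lap that was
    never supplied is an error — it usually means a mislabelled schedule.
    """
    by_key = {}
    for lap in laps:
        if lap.key in by_key:
            raise ValueError(f"duplicate lap key {lap.key}")
        by_key[lap.key] = lap
    for date, session, idx, reason in exclusions:
        key = (date, session, idx)
        if key not in by_key:
            raise ValueError(
                f"exclusion references unknown lap ({date.isoformat()}, "
                f"{session.name}, lap {idx}) ({reason})")
        del by_key[key]
    if not by_key:
        warnings.warn("campaign is empty after exclusions", stacklevel=2)
    return Campaign(laps=list(by_key.values()), excluded=list(exclusions))


@dataclass
class Route:
    """The monitoring route: an ordered WGS84 polyline with metric chainage."""

    lons: np.ndarray
    lats: np.ndarray
    projection: LocalProjection = field(init=False)
    line_m: LineString = field(init=False)

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        if self.lons.size != self.lats.size:
            raise ValueError("lon/lat arrays differ in length")
        if self.lons.size < 2:
            raise ValueError("route needs at least 2 vertices")
        self.projection = projection_for(self.lons, self.lats)
        self.line_m = projected_linestring(self.lons, self.lats, self.projection)
        if self.line_m.length <= 0:
            raise ValueError("route has zero length")

    @property
    def length_m(self) -> float:
        return float(self.line_m.length)

    @property
    def is_closed(self) -> bool:
        return bool(self.lons[0] == self.lons[-1] and self.lats[0] == self.lats[-1])

    def snap(self, lon: float, lat: float) -> tuple[float, float]:
        """Return (chainage_m, perpendicular offset_m) of a point."""
        from .geo import chainage_and_offset

        return chainage_and_offset(self.line_m, self.projection, lon, lat)

    def point_at(self, chainage: float) -> tuple[float, float]:
        from .geo import point_at_chainage

        return point_at_chainage(self.line_m, self.projection, chainage)


def _route_from_coords(coords: Sequence[Sequence[float]]) -> Route:
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("route geometry needs at least 2 vertices")
    return Route(lons=arr[:, 0], lats=arr[:, 1])


def read_route(source: str | Path) -> Route:
    """Read the route polyline from a GeoJSON LineString or a GPX 1.1 track.

    The file must contain exactly one line geometry; multi-geometry files are
    rejected with a message asking the user to extract the intended line.
    """
    path = Path(source)
    text = path.read_text()
    if path.suffix.lower() == ".gpx" or text.lstrip().startswith("<"):
        return _read_route_gpx(text)
    return _read_route_geojson(text)


def _read_route_geojson(text: str) -> Route:
    obj = json.loads(text)
    geoms: list[dict] = []

    def collect(g: dict) -> None:
        if g is None:
            return
        t = g.get("type")
        if t == "FeatureCollection":
            for f in g.get("features", []):
                collect(f)
        elif t == "Feature":
            collect(g.get("geometry"))
        elif t == "LineString":
            geoms.append(g)
        elif t == "MultiLineString":
            for coords in g.get("coordinates", []):
                geoms.append({"type": "LineString", "coordinates": coords})
        elif t is not None:
            raise ValueError(f"unsupported route geometry type {t!r}")

    collect(obj)
    if len(geoms) == 0:
        raise ValueError("no line geometry found in route file")
    if len(geoms) > 1:
        raise ValueError(
            f"route file contains {len(geoms)} line geometries; "
            "select the single intended route line"
        )
    return _route_from_coords(geoms[0]["coordinates"])


def _read_route_gpx(text: str) -> Route:
    root = etree.fromstring(text.encode())
    ns = {"g": root.nsmap.get(None, "http://www.topografix.com/GPX/1/1")}
    tracks = root.findall(".//g:trk", ns)
    if len(tracks) == 0:
        raise ValueError("no track found in GPX file")
    if len(tracks) > 1:
        raise ValueError(f"GPX file contains {len(tracks)} tracks; select one")
    pts = tracks[0].findall(".//g:trkpt", ns)
    coords = [(float(p.get("lon")), float(p.get("lat"))) for p in pts]
    return _route_from_coords(coords)


def _json_safe(value):
    if isinstance(value, float) and not math.isfinite(value):
        return None
    if isinstance(value, (np.floating, np.integer)):
        v = value.item()
        return _json_safe(v) if isinstance(v, float) else v
    if isinstance(value, Enum):
        return value.name
    if isinstance(value, (dt.date, dt.datetime)):
        return value.isoformat()
    return value


def write_geojson(features: Iterable[dict], path: str | Path) -> None:
    """Write features as an RFC 7946 FeatureCollection.

    Each feature is ``{"geometry": shapely geometry or GeoJSON dict,
    "properties": {...}}``. Non-finite numeric attributes are serialised as
    ``null`` (with a warning) so the output stays valid JSON.
    """
    out = {"type": "FeatureCollection", "features": []}
    for feat in features:
        geom = feat["geometry"]
        if hasattr(geom, "geom_type"):
            geom = mapping(geom)
        props = {}
        for k, v in feat.get("properties", {}).items():
            safe = _json_safe(v)
            if safe is None and v is not None and not isinstance(v, Enum):
                warnings.warn(f"non-finite attribute {k!r} serialised as null", stacklevel=2)
            props[k] = safe
        out["features"].append({"type": "Feature", "geometry": geom, "properties": props})
    Path(path).write_text(json.dumps(out, indent=1))


def read_geojson_features(path: str | Path) -> list[dict]:
    obj = json.loads(Path(path).read_text())
    if obj.get("type") != "FeatureCollection":
        raise ValueError("expected a FeatureCollection")
    return obj["features"]
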