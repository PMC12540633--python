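"""Synthetic transect campaigns with known ground truth.

The generator emulates the structure of a summer mobile-monitoring campaign:
a ~3.1 km closed city loop walked at ~1.5 m/s with a 1-Hz logging device,
four daily sessions (06:00, 12:00, 15:30, 20:00) of two laps each over
several clear-sky days, and afternoon questionnaire surveys with 15
participants at 12 stops.

The microclimate model is deliberately parsimonious — the analysis pipeline
only consumes *relative within-session contrasts*:

* air temperature: a diurnal sinusoid (mean, half-amplitude, peak hour) plus
  a small shade-coupled offset per route segment;
* global irradiance: a clear-sky half-sine between sunrise and sunset,
  scaled by ``1 - shade`` of the segment being walked, floored at zero;
* globe temperature: air temperature plus a radiant gain proportional to
  the local irradiance (a small grey globe overshoots air temperature by
  roughly 12 K in full summer sun);
* relative humidity: anti-phased with air temperature.

Per-segment shade fractions per session are the planted ground truth:
segments sunny in all four sessions are the expected consistent hotspots,
segments heavily shaded in all four (trees, underpasses) the expected
consistent coldspots. The second lap of each session is walked in the
opposite direction, a standard transect design that balances the diurnal
trend over the route so spatial contrasts, not start-time arithmetic,
dominate the extremes.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .transect_io import (Campaign, Lap, MetRecord, Route, Session,
                          read_device_log, read_route, write_geojson)
from .geo import LocalProjection

__all__ = [
    "Segment", "Climate", "SensorNoise", "VoteModel", "Schedule",
    "ScenarioConfig", "GroundTruth",
    "build_route", "simulate_lap", "simulate_campaign", "load_campaign",
    "simulate_survey", "ground_truth", "default_segments", "canonical_scenario",
    "simulate_enriched", "interval_jaccard", "recovery_jaccard",
]

_SESSION_NAMES = [s.name for s in Session.order()]


class Segment(BaseModel):
    """A route interval with a shade fraction per session."""

    start_m: float
    end_m: float
    shade: dict[str, float]  # session name -> fraction of sky blocked

    @field_validator("shade")
    @classmethod
    def _check_shade(cls, v: dict[str, float]) -> dict[str, float]:
        for name, frac in v.items():
            if name not in _SESSION_NAMES:
                raise ValueError(f"unknown session {name!r}")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"shade fraction {frac} outside [0, 1]")
        missing = set(_SESSION_NAMES) - set(v)
        if missing:
            raise ValueError(f"shade missing for sessions {sorted(missing)}")
        return v


class Climate(BaseModel):
    """Clear-sky diurnal forcing for a hot Central European summer day."""

    ta_mean: float = 24.0          # degC, daily mean air temperature
    ta_amplitude: float = 6.0      # K, half peak-to-trough
    ta_peak_hour: float = 15.5     # local solar-lagged maximum
    clear_sky_max: float = 900.0   # W/m2 at solar noon
    sunrise_hour: float = 4.75
    sunset_hour: float = 21.25
    rh_mean: float = 55.0          # %, anti-phased with temperature
    rh_amplitude: float = 15.0
    radiant_gain: float = 0.013    # K per W/m2: globe excess over air temp
    ta_shade_coupling: float = 1.0  # K: air temp offset between sun and shade
    surface_gain: float = 0.025    # K per W/m2 for the surface channel
    pressure_hpa: float = 1005.0


class SensorNoise(BaseModel):
    """Per-channel Gaussian sensor noise (standard deviations)."""

    air_temp: float = Field(0.2, ge=0)
    globe_temp: float = Field(0.3, ge=0)
    rel_humidity: float = Field(1.5, ge=0)
    irradiance: float = Field(20.0, ge=0)
    surface_temp: float = Field(0.5, ge=0)
    pressure: float = Field(0.2, ge=0)
    gps_m: float = Field(2.0, ge=0)

    @classmethod
    def zero(cls) -> "SensorNoise":
        return cls(air_temp=0, globe_temp=0, rel_humidity=0, irradiance=0,
                   surface_temp=0, pressure=0, gps_m=0)


class VoteModel(BaseModel):
    """Linear-latent ordinal vote generator around a neutral UTCI."""

    tsv_slope: float = 0.4        # sensation votes per K above neutral
    tcv_slope: float = 0.3        # comfort votes per K (applied negatively)
    neutral_utci: float = 35.0    # degC at which the average vote is neutral
    ordinal_noise_sd: float = Field(0.5, ge=0)  # scale units


class Exclusion(BaseModel):
    date: dt.date
    session: str
    lap_index: int
    reason: str = "unsuitable weather conditions"


class Schedule(BaseModel):
    dates: list[dt.date]
    sessions: list[str] = Field(default_factory=lambda: list(_SESSION_NAMES))
    laps_per_session: int = 2
    exclusions: list[Exclusion] = Field(default_factory=list)


class ScenarioConfig(BaseModel):
    """Full specification of a synthetic campaign."""

    route_length_m: float = 3100.0
    route_center_lon: float = 13.7373
    route_center_lat: float = 51.0405
    route_vertex_spacing_m: float = 25.0
    segments: list[Segment]
    climate: Climate = Field(default_factory=Climate)
    sensor_noise: SensorNoise = Field(default_factory=SensorNoise)
    walking_speed: float = Field(1.5, gt=0)  # m/s
    schedule: Schedule
    vote_model: VoteModel = Field(default_factory=VoteModel)
    n_participants: int = 15
    stops: dict[int, float] = Field(default_factory=dict)  # stop id -> chainage m
    survey_dates: list[dt.date] = Field(default_factory=list)
    reverse_second_lap: bool = True
    seed: int = 0


def build_route(scenario: ScenarioConfig) -> Route:
    """Closed loop of the configured polyline length.

    A regular polygon in the local metric frame, with the circumradius chosen
    so the *polyline* (chord) length equals ``route_length_m`` exactly.
    """
    n = max(8, int(round(scenario.route_length_m / scenario.route_vertex_spacing_m)))
    r = scenario.route_length_m / (2 * n * math.sin(math.pi / n))
    theta = np.linspace(0.0, 2 * math.pi, n + 1)  # first == last: closed
    x, y = r * np.cos(theta), r * np.sin(theta)
    proj = LocalProjection(scenario.route_center_lat, scenario.route_center_lon)
    lon, lat = proj.inverse(x, y)
    return Route(lons=lon, lats=lat)


def _segment_arrays(scenario: ScenarioConfig):
    segs = sorted(scenario.segments, key=lambda s: s.start_m)
    starts = np.array([s.start_m for s in segs])
    shade = {name: np.array([s.shade[name] for s in segs]) for name in _SESSION_NAMES}
    return starts, shade


def shade_at(scenario: ScenarioConfig, chainage, session: Session):
    """Shade fraction of the segment containing each chainage (0.5 if uncovered)."""
    starts, shade = _segment_arrays(scenario)
    c = np.asarray(chainage, dtype=float)
    idx = np.clip(np.searchsorted(starts, c, side="right") - 1, 0, len(starts) - 1)
    segs = sorted(scenario.segments, key=lambda s: s.start_m)
    ends = np.array([s.end_m for s in segs])
    vals = shade[session.name][idx]
    return np.where((c >= starts[idx]) & (c < ends[idx]), vals, 0.5)


def _lap_seed(scenario: ScenarioConfig, date: dt.date, session: Session,
              lap_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [scenario.seed, date.toordinal(), Session.order().index(session), lap_index])


def simulate_lap(scenario: ScenarioConfig, date: dt.date, session: Session,
                 lap_index: int, seed: np.random.SeedSequence | int | None = None
                 ) -> list[MetRecord]:
    """Generate the 1-Hz device records of one lap (deterministic per seed)."""
    route = build_route(scenario)
    length = route.length_m
    if length <= 0:
        raise ValueError("zero-length route")
    v = scenario.walking_speed
    n = int(math.ceil(length / v))  # chainage stays within [0, length]
    if seed is None:
        seed = _lap_seed(scenario, date, session, lap_index)
    rng = np.random.default_rng(seed)

    i = np.arange(n)
    lap_duration = n  # seconds, ~35 min at default speed and length
    start_hour = session.nominal_start_hour + (lap_index - 1) * lap_duration / 3600.0
    hours = start_hour + i / 3600.0
    forward = not (scenario.reverse_second_lap and lap_index % 2 == 0)
    chain = v * i if forward else np.clip(length - v * i, 0.0, length)

    cl = scenario.climate
    phase = 2 * math.pi * (hours - cl.ta_peak_hour) / 24.0
    ta_base = cl.ta_mean + cl.ta_amplitude * np.cos(phase)
    day_frac = (hours - cl.sunrise_hour) / (cl.sunset_hour - cl.sunrise_hour)
    s0 = cl.clear_sky_max * np.clip(np.sin(math.pi * np.clip(day_frac, 0, 1)), 0, None)
    sh = shade_at(scenario, chain, session)

    no = scenario.sensor_noise
    s = np.clip(s0 * (1.0 - sh) + rng.normal(0, no.irradiance, n), 0.0, None)
    ta = ta_base + cl.ta_shade_coupling * (0.5 - sh) + rng.normal(0, no.air_temp, n)
    tg = ta + cl.radiant_gain * s + rng.normal(0, no.globe_temp, n)
    rh = np.clip(cl.rh_mean - cl.rh_amplitude * np.cos(phase)
                 + rng.normal(0, no.rel_humidity, n), 5.0, 100.0)
    tsurf = ta + cl.surface_gain * s + rng.normal(0, no.surface_temp, n)
    p = cl.pressure_hpa + rng.normal(0, no.pressure, n)

    # positions: route point at chainage plus isotropic GNSS jitter
    pts = [route.line_m.interpolate(float(c)) for c in chain]
    x = np.array([pt.x for pt in pts]) + rng.normal(0, no.gps_m, n)
    y = np.array([pt.y for pt in pts]) + rng.normal(0, no.gps_m, n)
    lon, lat = route.projection.inverse(x, y)

    base = dt.datetime.combine(date, dt.time(0)) + dt.timedelta(hours=start_hour)
    base = base.replace(microsecond=0)
    records = [
        MetRecord(
            timestamp=base + dt.timedelta(seconds=int(k)),
            lat=float(lat[k]), lon=float(lon[k]),
            air_temp=float(ta[k]), rel_humidity=float(rh[k]),
            pressure=float(p[k]), surface_temp=float(tsurf[k]),
            globe_temp=float(tg[k]), global_irradiance=float(s[k]),
        )
        for k in i
    ]
    return records


def _lap_id(date: dt.date, session: Session, lap_index: int) -> str:
    return f"{date.isoformat()}_{session.name}_{lap_index}"


def scheduled_keys(schedule: Schedule) -> list[tuple[dt.date, Session, int]]:
    return [(d, Session[s], li)
            for d in schedule.dates
            for s in schedule.sessions
            for li in range(1, schedule.laps_per_session + 1)]


def simulate_campaign(scenario: ScenarioConfig, out_dir: str | Path) -> dict:
    """Write a full on-disk campaign: lap CSVs, route, stops and a manifest.

    Excluded laps are not written (they stand for discarded field data); the
    manifest records both the retained laps and the exclusions. An exclusion
    that references a lap not on the schedule is a configuration error.
    """
    out = Path(out_dir)
    (out / "laps").mkdir(parents=True, exist_ok=True)
    keys = scheduled_keys(scenario.schedule)
    excl = {(e.date, Session[e.session], e.lap_index): e.reason
            for e in scenario.schedule.exclusions}
    unknown = set(excl) - set(keys)
    if unknown:
        raise ValueError(f"exclusions reference unscheduled laps: {sorted(unknown)}")

    route = build_route(scenario)
    write_geojson([{
        "geometry": {"type": "LineString",
                     "coordinates": [[float(a), float(b)]
                                     for a, b in zip(route.lons, route.lats)]},
        "properties": {"name": "monitoring route", "length_m": route.length_m},
    }], out / "route.geojson")

    stop_feats = []
    for sid, chain in sorted(scenario.stops.items()):
        lon, lat = route.point_at(chain)
        stop_feats.append({
            "geometry": {"type": "Point", "coordinates": [lon, lat]},
            "properties": {"stop_id": sid, "chainage_m": chain},
        })
    write_geojson(stop_feats, out / "stops.geojson")

    manifest: dict = {"route": "route.geojson", "stops": "stops.geojson",
                      "seed": scenario.seed, "laps": [], "excluded": []}
    for date, session, li in keys:
        if (date, session, li) in excl:
            manifest["excluded"].append({
                "date": date.isoformat(), "session": session.name,
                "lap_index": li, "reason": excl[(date, session, li)]})
            continue
        records = simulate_lap(scenario, date, session, li)
        fname = f"laps/{_lap_id(date, session, li)}.csv"
        _write_device_csv(records, out / fname)
        manifest["laps"].append({"date": date.isoformat(), "session": session.name,
                                 "lap_index": li, "file": fname})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_device_csv(records: Sequence[MetRecord], path: Path) -> None:
    header = ("timestamp,lat,lon,air_temp_c,rh_pct,pressure_hpa,"
              "surface_temp_c,globe_temp_c,irradiance_wm2\n")
    lines = [header]
    for r in records:
        lines.append(
            f"{r.timestamp.isoformat()},{r.lat:.7f},{r.lon:.7f},{r.air_temp:.3f},"
            f"{r.rel_humidity:.2f},{r.pressure:.2f},{r.surface_temp:.3f},"
            f"{r.globe_temp:.3f},{r.global_irradiance:.2f}\n")
    path.write_text("".join(lines))


def load_campaign(campaign_dir: str | Path) -> tuple[Campaign, Route, dict[int, tuple[float, float]]]:
    """Read a simulated (or equivalently structured) campaign back from disk."""
    cdir = Path(campaign_dir)
    manifest = json.loads((cdir / "manifest.json").read_text())
    laps = []
    for entry in manifest["laps"]:
        result = read_device_log(cdir / entry["file"])
        date = dt.date.fromisoformat(entry["date"])
        session = Session[entry["session"]]
        laps.append(Lap(lap_id=_lap_id(date, session, entry["lap_index"]),
                        date=date, session=session,
                        lap_index=entry["lap_index"], records=result.records))
    excluded = [(dt.date.fromisoformat(e["date"]), Session[e["session"]],
                 e["lap_index"], e["reason"]) for e in manifest["excluded"]]
    campaign = Campaign(laps=laps, excluded=excluded)
    route = read_route(cdir / manifest["route"])
    stops: dict[int, tuple[float, float]] = {}
    if (cdir / manifest["stops"]).exists():
        feats = json.loads((cdir / manifest["stops"]).read_text())["features"]
        for f in feats:
            lon, lat = f["geometry"]["coordinates"]
            stops[int(f["properties"]["stop_id"])] = (lon, lat)
    return campaign, route, stops


def simulate_survey(scenario: ScenarioConfig,
                    stop_utci: Mapping,
                    seed: np.random.SeedSequence | int | None = None) -> list[dict]:
    """Generate ordinal vote rows from per-stop UTCI.

    ``stop_utci`` maps either stop id -> UTCI (single survey date) or
    date -> {stop id -> UTCI}. Latent votes are linear in (UTCI - neutral)
    with Gaussian noise, then rounded and clipped to the scales; preference
    follows the comfort sign (uncomfortable and feeling warm -> wants cooler).
    """
    vm = scenario.vote_model
    if seed is None:
        seed = np.random.SeedSequence([scenario.seed, 7919])
    rng = np.random.default_rng(seed)
    if stop_utci and not isinstance(next(iter(stop_utci.values())), Mapping):
        date0 = scenario.survey_dates[0] if scenario.survey_dates else dt.date(2022, 6, 19)
        by_date: Mapping = {date0: stop_utci}
    else:
        by_date = stop_utci

    rows: list[dict] = []
    for date in sorted(by_date):
        for p in range(1, scenario.n_participants + 1):
            for sid in sorted(by_date[date]):
                u = by_date[date][sid] - vm.neutral_utci
                tsv_lat = vm.tsv_slope * u + rng.normal(0, vm.ordinal_noise_sd)
                tcv_lat = -abs(vm.tcv_slope) * u + rng.normal(0, vm.ordinal_noise_sd)
                tsv = int(np.clip(np.round(tsv_lat), -3, 3))
                tcv = int(np.clip(np.round(tcv_lat), -2, 2))
                pref = 0 if tcv >= 0 else (-1 if tsv > 0 else 1)
                rows.append({"participant_id": f"P{p:02d}", "stop_id": sid,
                             "date": date.isoformat(), "tsv": tsv, "tcv": tcv,
                             "preference": pref})
    return rows


@dataclass(frozen=True)
class GroundTruth:
    """Analytically expected extremes of a scenario."""

    hot_by_session: dict[Session, list[tuple[float, float]]]
    cold_by_session: dict[Session, list[tuple[float, float]]]
    consistent_hot: list[tuple[float, float]]
    consistent_cold: list[tuple[float, float]]
    neutral_utci: float


def _intersect_interval_sets(sets: Sequence[Sequence[tuple[float, float]]]
                             ) -> list[tuple[float, float]]:
    current = list(sets[0])
    for nxt in sets[1:]:
        merged = []
        for a1, b1 in current:
            for a2, b2 in nxt:
                lo, hi = max(a1, a2), min(b1, b2)
                if lo < hi:
                    merged.append((lo, hi))
        current = merged
    return sorted(current)


def ground_truth(scenario: ScenarioConfig, sun_threshold: float = 0.25,
                 shade_threshold: float = 0.75) -> GroundTruth:
    """Expected hot/cold intervals per session and their four-way intersections.

    A segment counts as a hot candidate in a session when its shade is at or
    below ``sun_threshold``, as a cold candidate at or above
    ``shade_threshold``; consistent intervals are the interval intersections
    across all four sessions.
    """
    hot: dict[Session, list[tuple[float, float]]] = {}
    cold: dict[Session, list[tuple[float, float]]] = {}
    for session in Session:
        hot[session] = [(s.start_m, s.end_m) for s in scenario.segments
                        if s.shade[session.name] <= sun_threshold]
        cold[session] = [(s.start_m, s.end_m) for s in scenario.segments
                         if s.shade[session.name] >= shade_threshold]
    return GroundTruth(
        hot_by_session=hot, cold_by_session=cold,
        consistent_hot=_intersect_interval_sets([hot[s] for s in Session.order()]),
        consistent_cold=_intersect_interval_sets([cold[s] for s in Session.order()]),
        neutral_utci=scenario.vote_model.neutral_utci,
    )


# ---------------------------------------------------------------------------
# canonical scenario: a city-centre loop with four consistently sunny and
# four consistently shaded stretches, everything else varying with the sun
# ---------------------------------------------------------------------------

_HOT_SEGMENTS = [(240.0, 275.0), (820.0, 855.0), (1450.0, 1485.0), (2300.0, 2335.0)]
_COLD_SEGMENTS = [(480.0, 515.0), (1080.0, 1115.0), (1900.0, 1935.0), (2700.0, 2735.0)]
_FILLER_CYCLE = [0.45, 0.60, 0.75, 0.60]  # rotated per filler segment


def default_segments(route_length_m: float = 3100.0) -> list[Segment]:
    """Segment layout with planted consistent hot/cold stretches.

    Four 35-m stretches are sunny in every session (south-facing facades,
    open squares), four are heavily shaded in every session (underpasses,
    dense tree cover). The remaining fillers rotate a moderate shade pattern
    across sessions, mimicking canyon walls that swap sun exposure as the
    day progresses — so no filler is an extreme in all four sessions.
    """
    planted = (
        [(a, b, {n: 0.02 for n in _SESSION_NAMES}) for a, b in _HOT_SEGMENTS]
        + [(a, b, {n: 0.95 for n in _SESSION_NAMES}) for a, b in _COLD_SEGMENTS]
    )
    planted.sort(key=lambda t: t[0])
    fillers = []
    edges = [0.0] + [x for a, b, _ in planted for x in (a, b)] + [route_length_m]
    fi = 0
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a <= 0:
            continue
        shade = {name: _FILLER_CYCLE[(j + fi) % 4]
                 for j, name in enumerate(_SESSION_NAMES)}
        fillers.append((a, b, shade))
        fi += 1
    return [Segment(start_m=a, end_m=b, shade=sh) for a, b, sh in planted + fillers]


CANONICAL_DATES = [dt.date(2022, 6, 19), dt.date(2022, 6, 23), dt.date(2022, 7, 19),
               dt.date(2022, 7, 25), dt.date(2022, 8, 16), dt.date(2022, 8, 17)]

CANONICAL_EXCLUSIONS = [
    Exclusion(date=dt.date(2022, 8, 16), session="AFTERNOON", lap_index=1),
    Exclusion(date=dt.date(2022, 8, 16), session="AFTERNOON", lap_index=2),
    Exclusion(date=dt.date(2022, 7, 25), session="EVENING", lap_index=2),
]

DEFAULT_STOPS = {1: 120.0, 2: 200.0, 3: 257.5, 4: 340.0, 5: 420.0, 6: 497.5,
                 7: 560.0, 8: 640.0, 9: 720.0, 10: 790.0, 11: 837.5, 12: 900.0}


def canonical_scenario(seed: int = 0, *, dates: list[dt.date] | None = None,
                   exclusions: list[Exclusion] | None = None,
                   noise: SensorNoise | None = None) -> ScenarioConfig:
    """The canonical six-day campaign scenario (45 retained laps).

    ``dates`` may be shortened (with ``exclusions=[]``) for faster runs; all
    other conditions (route, segments, climate, noise, votes) are fixed.
    """
    if dates is None:
        dates = CANONICAL_DATES
        if exclusions is None:
            exclusions = CANONICAL_EXCLUSIONS
    return ScenarioConfig(
        segments=default_segments(),
        schedule=Schedule(dates=dates, exclusions=exclusions or []),
        sensor_noise=noise if noise is not None else SensorNoise(),
        stops=dict(DEFAULT_STOPS),
        survey_dates=dates[: min(3, len(dates))],
        seed=seed,
    )


def simulate_enriched(scenario: ScenarioConfig, wind=None, spec=None
                      ) -> tuple[dict, Route]:
    """Simulate the scheduled laps and enrich them in memory (no disk I/O).

    Returns ``(enriched, route)`` where ``enriched`` maps lap keys
    ``(date, session, lap_index)`` to ThermalRecord sequences — the input
    shape expected by :func:`heatwalk.hotspots.run_prioritisation`.
    """
    from .microclimate import GlobeSpec, WindConfig, enrich_lap

    wind = wind if wind is not None else WindConfig()
    spec = spec if spec is not None else GlobeSpec()
    excl = {(e.date, Session[e.session], e.lap_index)
            for e in scenario.schedule.exclusions}
    route = build_route(scenario)
    enriched: dict = {}
    for key in scheduled_keys(scenario.schedule):
        if key in excl:
            continue
        date, session, li = key
        lap = Lap(lap_id=_lap_id(date, session, li), date=date, session=session,
                  lap_index=li, records=simulate_lap(scenario, date, session, li))
        enriched[key], _ = enrich_lap(lap, wind, spec)
    return enriched, route


def interval_jaccard(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Jaccard overlap |a∩b| / |a∪b| of two chainage intervals."""
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0.0:
        return 0.0
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union


def recovery_jaccard(zone_intervals: Sequence[tuple[float, float]],
                     truth_intervals: Sequence[tuple[float, float]]) -> float:
    """Mean, over ground-truth intervals, of the best-matching zone overlap.

    A missed truth interval contributes zero, so the score penalises both
    missed and badly delimited zones (extra spurious zones are judged by the
    caller, not here).
    """
    if not truth_intervals:
        return float("nan")
    scores = []
    for t in truth_intervals:
        best = max((interval_jaccard(z, t) for z in zone_intervals), default=0.0)
        scores.append(best)
    return float(np.mean(scores))
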