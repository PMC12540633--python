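"""Extreme-UTCI prioritisation along the route.

The procedure mirrors how planners turn transect heat maps into a short list
of intervention sites:

1. per lap, take the hottest (or coldest) 5% of UTCI records — nearest-rank,
   i.e. exactly ``ceil(fraction * n)`` records;
2. snap those records onto the route polyline (linear referencing), dropping
   points farther than a tolerance;
3. pool each session's laps (all days) and single-linkage cluster the snapped
   points along chainage, discarding clusters of three or fewer points;
4. intersect the four sessions' cluster intervals: a *consistent zone* is a
   stretch of route that is extreme at 06:00, 12:00, 15:30 and 20:00 alike.

Buffered intersection (step 4) tolerates session-to-session drift of cluster
edges: intervals are dilated by ``intersect_buffer_m`` before intersecting
and the result eroded by the same amount, so identical inputs round-trip
unchanged and the buffer never inflates a zone.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .microclimate import ThermalRecord
from .transect_io import Route, Session

logger = logging.getLogger(__name__)

__all__ = [
    "ExtremeKind",
    "ThresholdConfig",
    "ExtremePoint",
    "Cluster",
    "ConsistentZone",
    "PrioritisationResult",
    "extract_extremes",
    "snap_to_route",
    "cluster_session",
    "intersect_sessions",
    "run_prioritisation",
]


class ExtremeKind(Enum):
    HOT = "hot"
    COLD = "cold"


@dataclass(frozen=True)
class ThresholdConfig:
    """Tunable thresholds of the prioritisation procedure (all distances in m)."""

    fraction: float = 0.05
    min_cluster_points: int = 4   # "three or fewer" isolated points are dropped
    snap_max_m: float = 30.0
    cluster_gap_m: float = 25.0
    intersect_buffer_m: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 0.5):
            raise ValueError(f"fraction {self.fraction} outside (0, 0.5]")
        if self.min_cluster_points < 1:
            raise ValueError("min_cluster_points must be >= 1")
        for name in ("snap_max_m", "cluster_gap_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.intersect_buffer_m < 0:
            raise ValueError("intersect_buffer_m must be >= 0")


@dataclass(frozen=True)
class ExtremePoint:
    """One extreme-UTCI record, linearly referenced onto the route."""

    record: ThermalRecord
    kind: ExtremeKind
    lap_id: str
    session: Session
    utci: float
    chainage_m: float = math.nan
    snap_offset_m: float = math.nan


@dataclass(frozen=True)
class Cluster:
    kind: ExtremeKind
    session: Session
    start_m: float
    end_m: float
    points: tuple[ExtremePoint, ...]
    mean_utci: float
    peak_utci: float

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start_m, self.end_m)

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ConsistentZone:
    kind: ExtremeKind
    start_m: float
    end_m: float
    contributing: Mapping[Session, Cluster]

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start_m, self.end_m)

    @property
    def peak_utci(self) -> float:
        peaks = [c.peak_utci for c in self.contributing.values()]
        return max(peaks) if self.kind is ExtremeKind.HOT else min(peaks)


def extract_extremes(lap_records: Sequence[ThermalRecord], fraction: float,
                     kind: ExtremeKind, lap_id: str = "",
                     session: Session | None = None) -> list[ExtremePoint]:
    """Nearest-rank extreme extraction: exactly ``ceil(fraction * n)`` records.

    For HOT, every returned UTCI is >= every non-returned UTCI (mirrored for
    COLD); ties at the boundary are broken in favour of earlier timestamps.
    Returned points are in record (time) order and not yet snapped.
    """
    if not (0.0 < fraction <= 0.5):
        raise ValueError(f"fraction {fraction} outside (0, 0.5]")
    n = len(lap_records)
    if n == 0:
        raise ValueError("cannot extract extremes from an empty lap")
    k = math.ceil(fraction * n)
    vals = np.array([r.utci for r in lap_records])
    if np.ptp(vals) == 0.0:
        warnings.warn(
            f"lap {lap_id or '<unnamed>'}: degenerate constant UTCI distribution; "
            "extreme selection falls back to record order", stacklevel=2)
    sign = -1.0 if kind is ExtremeKind.HOT else 1.0
    # stable sort on (signed value, record index) implements the tie-break
    order = np.lexsort((np.arange(n), sign * vals))
    chosen = sorted(order[:k])
    return [
        ExtremePoint(record=lap_records[i], kind=kind, lap_id=lap_id,
                     session=session if session is not None else Session.AFTERNOON,
                     utci=float(vals[i]))
        for i in chosen
    ]


def snap_to_route(points: Iterable[ExtremePoint], route: Route,
                  snap_max_m: float = 30.0) -> tuple[list[ExtremePoint], list[ExtremePoint]]:
    """Linear-reference points onto the route.

    Returns ``(snapped, dropped)``: each snapped point carries the chainage of
    the nearest location on the polyline; points farther than ``snap_max_m``
    are dropped and reported. If everything is dropped the route file is
    almost certainly the wrong one, so that is an error.
    """
    snapped: list[ExtremePoint] = []
    dropped: list[ExtremePoint] = []
    points = list(points)
    for p in points:
        chain, off = route.snap(p.record.lon, p.record.lat)
        q = ExtremePoint(record=p.record, kind=p.kind, lap_id=p.lap_id,
                         session=p.session, utci=p.utci,
                         chainage_m=chain, snap_offset_m=off)
        (snapped if off <= snap_max_m else dropped).append(q)
    if points and not snapped:
        raise ValueError(
            f"all {len(points)} points farther than {snap_max_m} m from the route; "
            "check that the route file matches the campaign")
    return snapped, dropped


def cluster_session(points: Sequence[ExtremePoint], cluster_gap_m: float = 25.0,
                    min_cluster_points: int = 4) -> tuple[list[Cluster], list[ExtremePoint]]:
    """Single-linkage 1-D clustering of snapped points along chainage.

    Consecutive (chainage-sorted) points closer than ``cluster_gap_m`` join
    the same cluster. Clusters with fewer than ``min_cluster_points`` members
    — the isolated points — are omitted and returned separately.
    """
    if not points:
        return [], []
    pts = sorted(points, key=lambda p: p.chainage_m)
    groups: list[list[ExtremePoint]] = [[pts[0]]]
    for prev, cur in zip(pts, pts[1:]):
        if cur.chainage_m - prev.chainage_m <= cluster_gap_m:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    clusters: list[Cluster] = []
    omitted: list[ExtremePoint] = []
    for g in groups:
        if len(g) < min_cluster_points:
            omitted.extend(g)
            continue
        utcis = [p.utci for p in g]
        kind = g[0].kind
        clusters.append(Cluster(
            kind=kind, session=g[0].session,
            start_m=g[0].chainage_m, end_m=g[-1].chainage_m,
            points=tuple(g), mean_utci=float(np.mean(utcis)),
            peak_utci=float(max(utcis) if kind is ExtremeKind.HOT else min(utcis)),
        ))
    return clusters, omitted


def _intersect_buffered(intervals: Sequence[tuple[float, float]],
                        buffer_m: float) -> tuple[float, float] | None:
    """Intersect dilated intervals, then erode the result by the buffer."""
    lo = max(a - buffer_m for a, _ in intervals)
    hi = min(b + buffer_m for _, b in intervals)
    lo, hi = lo + buffer_m, hi - buffer_m
    return (lo, hi) if lo <= hi else None


def intersect_sessions(clusters_by_session: Mapping[Session, Sequence[Cluster]],
                       intersect_buffer_m: float = 10.0) -> list[ConsistentZone]:
    """Consistent zones: one buffered cluster interval per session, intersected.

    Requires all four sessions as keys (possibly with empty lists — any empty
    session means no zone can be consistent). All cross-session combinations
    are intersected; non-maximal results (intervals contained in another
    zone's interval) are pruned; zones are sorted by start chainage.
    """
    missing = set(Session) - set(clusters_by_session)
    if missing:
        raise ValueError(f"sessions missing from cluster map: {sorted(s.name for s in missing)}")
    session_order = Session.order()
    lists = [list(clusters_by_session[s]) for s in session_order]
    if any(not lst for lst in lists):
        return []
    kinds = {c.kind for lst in lists for c in lst}
    if len(kinds) > 1:
        raise ValueError("mixed HOT/COLD clusters in one intersection")

    candidates: list[ConsistentZone] = []
    for combo in itertools.product(*lists):
        iv = _intersect_buffered([c.interval for c in combo], intersect_buffer_m)
        if iv is None:
            continue
        candidates.append(ConsistentZone(
            kind=combo[0].kind, start_m=iv[0], end_m=iv[1],
            contributing=dict(zip(session_order, combo)),
        ))
    # prune zones whose interval is contained in a strictly larger zone
    keep: list[ConsistentZone] = []
    for z in candidates:
        if any(o is not z and o.start_m <= z.start_m and z.end_m <= o.end_m
               and (o.end_m - o.start_m) > (z.end_m - z.start_m) for o in candidates):
            continue
        if any(k.start_m == z.start_m and k.end_m == z.end_m for k in keep):
            continue
        keep.append(z)
    keep.sort(key=lambda z: (z.start_m, z.end_m))
    return keep


@dataclass
class PrioritisationResult:
    hot_zones: list[ConsistentZone]
    cold_zones: list[ConsistentZone]
    clusters: dict[ExtremeKind, dict[Session, list[Cluster]]]
    qc: dict = field(default_factory=dict)

    def summary_rows(self) -> list[dict]:
        rows = []
        for kind, zones in ((ExtremeKind.HOT, self.hot_zones),
                            (ExtremeKind.COLD, self.cold_zones)):
            for z in zones:
                rows.append({
                    "kind": kind.value,
                    "start_m": round(z.start_m, 1),
                    "end_m": round(z.end_m, 1),
                    "length_m": round(z.end_m - z.start_m, 1),
                    "sessions": len(z.contributing),
                    "peak_utci": round(z.peak_utci, 2),
                })
        return rows


def run_prioritisation(enriched: Mapping[tuple, Sequence[ThermalRecord]],
                       route: Route,
                       config: ThresholdConfig = ThresholdConfig()) -> PrioritisationResult:
    """End-to-end prioritisation over an enriched campaign.

    ``enriched`` maps lap keys ``(date, session, lap_index)`` to that lap's
    ThermalRecord sequence. The pipeline is a pure function of its inputs:
    extraction per lap, snapping, per-session pooling over all days,
    clustering, and the four-way session intersection, for both HOT and COLD
    kinds.
    """
    if not enriched:
        raise ValueError("no enriched laps supplied")

    present_sessions = {key[1] for key in enriched}
    missing = set(Session) - present_sessions
    qc: dict = {"dropped_snap": 0, "omitted_isolated": 0, "missing_sessions": sorted(s.name for s in missing)}
    if missing:
        warnings.warn(
            "campaign lacks sessions "
            f"{sorted(s.name for s in missing)}; consistent-zone intersection will be empty",
            stacklevel=2)

    clusters: dict[ExtremeKind, dict[Session, list[Cluster]]] = {}
    zones: dict[ExtremeKind, list[ConsistentZone]] = {}
    for kind in ExtremeKind:
        per_session: dict[Session, list[ExtremePoint]] = {s: [] for s in Session}
        keys = sorted(enriched, key=lambda k: (k[0], k[1].nominal_start_hour, k[2]))
        for (date, session, lap_index) in keys:
            records = enriched[(date, session, lap_index)]
            lap_id = f"{date}_{session.name}_{lap_index}"
            pts = extract_extremes(records, config.fraction, kind,
                                   lap_id=lap_id, session=session)
            snapped, dropped = snap_to_route(pts, route, config.snap_max_m)
            qc["dropped_snap"] += len(dropped)
            per_session[session].extend(snapped)
        session_clusters: dict[Session, list[Cluster]] = {}
        for session in Session:
            cl, omitted = cluster_session(per_session[session],
                                          config.cluster_gap_m,
                                          config.min_cluster_points)
            qc["omitted_isolated"] += len(omitted)
            session_clusters[session] = cl
        clusters[kind] = session_clusters
        if missing:
            zones[kind] = []
        else:
            zones[kind] = intersect_sessions(session_clusters, config.intersect_buffer_m)

    return PrioritisationResult(
        hot_zones=zones[ExtremeKind.HOT],
        cold_zones=zones[ExtremeKind.COLD],
        clusters=clusters,
        qc=qc,
    )
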