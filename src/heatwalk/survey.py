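"""Questionnaire analysis: subjective votes versus measured UTCI.

Participants answer at fixed stops along a sub-route, on ASHRAE-style
ordinal scales: thermal sensation vote (TSV, -3 cool ... +3 hot, 7 points),
thermal comfort vote (TCV, -2 very uncomfortable ... +2 comfortable,
5 points) and thermal preference (-1 cooler / 0 no change / +1 warmer).
Votes are pooled over participants and survey dates into per-stop means,
matched to the mean UTCI of transect records within a radius of each stop
during the concurrent afternoon lap, and compared by Pearson correlation.

The *neutral range* is the UTCI interval over which the fitted mean comfort
vote stays within a small band around zero — a reproducible ordinary
least squares reading of "where the average pedestrian is neither
comfortable nor uncomfortable".
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .microclimate import ThermalRecord
from .transect_io import Route

logger = logging.getLogger(__name__)

__all__ = [
    "SurveyResponse",
    "StopSummary",
    "ComparisonResult",
    "PedestrianPresence",
    "validate_responses",
    "stop_utci",
    "summarise_stops",
    "correlate",
    "neutral_range",
    "flag_discrepancies",
    "classify_pedestrian_presence",
]

TSV_SCALE = tuple(range(-3, 4))   # 7-point sensation scale
TCV_SCALE = tuple(range(-2, 3))   # 5-point comfort scale
PREF_SCALE = (-1, 0, 1)


@dataclass(frozen=True)
class SurveyResponse:
    participant_id: str
    stop_id: int     # 1..12
    date: dt.date
    tsv: int
    tcv: int
    preference: int


@dataclass
class StopSummary:
    stop_id: int
    n_votes: int
    mean_tsv: float
    mean_tcv: float
    tsv_spread: float   # sample SD of votes
    tcv_spread: float
    mean_utci: float = math.nan


@dataclass
class ComparisonResult:
    r_tsv_utci: float
    r_tcv_utci: float
    neutral_interval: tuple[float, float] | None
    discrepancy_stops: list[tuple[int, str]]


def validate_responses(raw_rows: Iterable[Mapping], n_stops: int = 12
                       ) -> tuple[list[SurveyResponse], list[str]]:
    """Validate raw vote rows against the ordinal scales.

    Out-of-scale votes and duplicate (participant, stop, date) entries are
    rejected with human-readable reasons; nothing is fatal here, but an empty
    valid set will make the downstream operations error out.
    """
    valid: list[SurveyResponse] = []
    report: list[str] = []
    seen: set[tuple] = set()
    for i, row in enumerate(raw_rows, start=1):
        try:
            pid = str(row["participant_id"])
            stop = int(row["stop_id"])
            date = row["date"]
            if isinstance(date, str):
                date = dt.date.fromisoformat(date)
            tsv, tcv, pref = int(row["tsv"]), int(row["tcv"]), int(row["preference"])
        except (KeyError, ValueError, TypeError) as exc:
            report.append(f"row {i}: malformed ({exc})")
            continue
        if not (1 <= stop <= n_stops):
            report.append(f"row {i}: stop_id {stop} outside 1..{n_stops}")
            continue
        if tsv not in TSV_SCALE:
            report.append(f"row {i}: tsv {tsv} outside 7-point scale -3..3")
            continue
        if tcv not in TCV_SCALE:
            report.append(f"row {i}: tcv {tcv} outside 5-point scale -2..2")
            continue
        if pref not in PREF_SCALE:
            report.append(f"row {i}: preference {pref} outside -1..1")
            continue
        key = (pid, stop, date)
        if key in seen:
            report.append(f"row {i}: duplicate vote for {key}")
            continue
        seen.add(key)
        valid.append(SurveyResponse(pid, stop, date, tsv, tcv, pref))
    return valid, report


def stop_utci(enriched_records: Sequence[ThermalRecord],
              stops: Mapping[int, tuple[float, float]],
              route: Route, radius_m: float = 25.0) -> tuple[dict[int, float], list[int]]:
    """Mean UTCI of the survey lap's records within ``radius_m`` of each stop.

    ``stops`` maps stop id to (lon, lat). Distances are Euclidean in the
    route's local metric frame. Stops with no records inside the radius are
    flagged (returned separately); if every stop is empty the lap and the
    stop layout do not match, which is an error.
    """
    proj = route.projection
    rx, ry = proj.forward(np.array([r.lon for r in enriched_records]),
                          np.array([r.lat for r in enriched_records]))
    utci = np.array([r.utci for r in enriched_records])
    means: dict[int, float] = {}
    empty: list[int] = []
    for sid, (lon, lat) in stops.items():
        sx, sy = proj.forward(lon, lat)
        mask = (rx - float(sx)) ** 2 + (ry - float(sy)) ** 2 <= radius_m ** 2
        if not mask.any():
            empty.append(sid)
        else:
            means[sid] = float(utci[mask].mean())
    if not means:
        raise ValueError("no transect records within radius of any stop; "
                         "check route/stop pairing and survey lap")
    return means, empty


def summarise_stops(responses: Sequence[SurveyResponse],
                    utci_by_stop: Mapping[int, float]) -> list[StopSummary]:
    """Pool votes over participants and dates into per-stop summaries."""
    if not responses:
        raise ValueError("no valid survey responses")
    out: list[StopSummary] = []
    for sid in sorted({r.stop_id for r in responses}):
        votes = [r for r in responses if r.stop_id == sid]
        tsv = np.array([v.tsv for v in votes], dtype=float)
        tcv = np.array([v.tcv for v in votes], dtype=float)
        out.append(StopSummary(
            stop_id=sid, n_votes=len(votes),
            mean_tsv=float(tsv.mean()), mean_tcv=float(tcv.mean()),
            tsv_spread=float(tsv.std(ddof=1)) if len(votes) > 1 else 0.0,
            tcv_spread=float(tcv.std(ddof=1)) if len(votes) > 1 else 0.0,
            mean_utci=float(utci_by_stop.get(sid, math.nan)),
        ))
    return out


def _paired(stop_summaries: Sequence[StopSummary]):
    usable = [s for s in stop_summaries if math.isfinite(s.mean_utci)]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 stops with votes and UTCI, have {len(usable)}")
    u = np.array([s.mean_utci for s in usable])
    tsv = np.array([s.mean_tsv for s in usable])
    tcv = np.array([s.mean_tcv for s in usable])
    return usable, u, tsv, tcv


def correlate(stop_summaries: Sequence[StopSummary]) -> tuple[float, float]:
    """Pearson r of per-stop mean TSV and mean TCV against mean UTCI."""
    _, u, tsv, tcv = _paired(stop_summaries)
    if np.ptp(u) == 0 or np.ptp(tsv) == 0 or np.ptp(tcv) == 0:
        raise ValueError("zero variance in a series; correlation undefined")
    r_tsv = float(stats.pearsonr(u, tsv).statistic)
    r_tcv = float(stats.pearsonr(u, tcv).statistic)
    return r_tsv, r_tcv


def neutral_range(stop_summaries: Sequence[StopSummary],
                  band: float = 0.25) -> tuple[float, float] | None:
    """UTCI interval where the fitted mean comfort vote lies within ±band.

    An OLS line ``tcv = a + b * UTCI`` is fitted to the per-stop means; the
    interval is the pre-image of [-band, +band], clipped to the observed UTCI
    span. Returns None (with a diagnostic log) when the fit never enters the
    band in-span — e.g. all votes comfortable, or a flat line off zero.
    """
    _, u, _, tcv = _paired(stop_summaries)
    b, a = np.polyfit(u, tcv, 1)
    lo_u, hi_u = float(u.min()), float(u.max())
    if abs(b) < 1e-12:
        if abs(a) <= band:
            return (lo_u, hi_u)
        logger.info("neutral_range: flat comfort fit at %.2f, outside ±%.2f band", a, band)
        return None
    u1, u2 = sorted(((-band - a) / b, (band - a) / b))
    lo, hi = max(u1, lo_u), min(u2, hi_u)
    if lo > hi:
        logger.info("neutral_range: fitted line does not enter the band within "
                    "the observed UTCI span [%.1f, %.1f]", lo_u, hi_u)
        return None
    return (float(lo), float(hi))


def flag_discrepancies(stop_summaries: Sequence[StopSummary],
                       z_threshold: float = 1.0) -> list[tuple[int, str]]:
    """Stops whose votes disagree with the measurement, with direction.

    Mean TSV and mean UTCI are standardised across stops; a stop is flagged
    when |z(vote) - z(UTCI)| exceeds the threshold. "perceived hotter" means
    the vote z-score sits above the UTCI z-score (pedestrians felt hotter
    than the index suggests), and vice versa.
    """
    usable, u, tsv, _ = _paired(stop_summaries)
    if np.std(u) == 0 or np.std(tsv) == 0:
        raise ValueError("zero variance; z-scores undefined")
    zu = (u - u.mean()) / u.std()
    zv = (tsv - tsv.mean()) / tsv.std()
    flags: list[tuple[int, str]] = []
    for s, d in zip(usable, zv - zu):
        if abs(d) > z_threshold:
            flags.append((s.stop_id, "perceived hotter" if d > 0 else "perceived cooler"))
    return flags


class PedestrianPresence(Enum):
    VERY_LOW = "very low"     # mean count <= 2
    MODERATE = "moderate"     # 3-5
    HIGH = "high"             # 6-15
    VERY_HIGH = "very high"   # > 15


def classify_pedestrian_presence(mean_count: float) -> PedestrianPresence:
    """Categorise average visible pedestrian counts (rounded half-up)."""
    if mean_count < 0:
        raise ValueError(f"negative pedestrian count {mean_count}")
    n = math.floor(mean_count + 0.5)  # round half-up, also for .5 values
    if n <= 2:
        return PedestrianPresence.VERY_LOW
    if n <= 5:
        return PedestrianPresence.MODERATE
    if n <= 15:
        return PedestrianPresence.HIGH
    return PedestrianPresence.VERY_HIGH
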