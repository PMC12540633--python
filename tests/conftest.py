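"""Shared fixtures: small synthetic campaigns reused across test modules."""

from __future__ import annotations

import datetime as dt

import pytest

from heatwalk import synthetic_data as sd
from heatwalk.microclimate import enrich_lap
from heatwalk.survey import stop_utci, summarise_stops, validate_responses
from heatwalk.transect_io import Lap, Session

DEMO_DATE = dt.date(2022, 6, 19)


@pytest.fixture(scope="session")
def demo_scenario() -> sd.ScenarioConfig:
    """One-day demo campaign with the canonical planted segment layout."""
    return sd.canonical_scenario(seed=11, dates=[DEMO_DATE], exclusions=[])


@pytest.fixture(scope="session")
def demo_enriched(demo_scenario):
    """Enriched one-day campaign: (enriched lap map, route)."""
    return sd.simulate_enriched(demo_scenario)


@pytest.fixture(scope="session")
def afternoon_lap(demo_scenario) -> Lap:
    records = sd.simulate_lap(demo_scenario, DEMO_DATE, Session.AFTERNOON, 1)
    return Lap(lap_id="aft1", date=DEMO_DATE, session=Session.AFTERNOON,
               lap_index=1, records=records)


@pytest.fixture(scope="session")
def demo_stop_summaries(demo_scenario, demo_enriched, afternoon_lap):
    """Per-stop summaries from a simulated afternoon survey."""
    _, route = demo_enriched
    enr, _ = enrich_lap(afternoon_lap)
    stops = {sid: route.point_at(c) for sid, c in demo_scenario.stops.items()}
    means, _empty = stop_utci(enr, stops, route, radius_m=25.0)
    rows = sd.simulate_survey(demo_scenario, {DEMO_DATE: means}, seed=5)
    valid, report = validate_responses(rows)
    assert not report
    return summarise_stops(valid, means)
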