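"""Extraction, snapping, clustering and session intersection.

The extraction and clustering operations are checked against independent
brute-force references: a full sort with explicit tie-breaking, and a
quadratic transitive-closure single-linkage grouping.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pytest

from heatwalk.hotspots import (Cluster, ExtremeKind, ExtremePoint,
                               ThresholdConfig, cluster_session,
                               extract_extremes, intersect_sessions,
                               run_prioritisation, snap_to_route)
from heatwalk.microclimate import ThermalRecord, StressCategory
from heatwalk.transect_io import Route, Session
from heatwalk import synthetic_data as sd


def _thermal(utci: float, k: int, lon=13.73, lat=51.04) -> ThermalRecord:
    return ThermalRecord(
        timestamp=dt.datetime(2022, 6, 19, 12, 0) + dt.timedelta(seconds=k),
        lat=lat, lon=lon, air_temp=25.0, rel_humidity=50.0, pressure=1005.0,
        surface_temp=30.0, globe_temp=30.0, global_irradiance=500.0,
        vapour_pressure=11.7, tmrt=40.0, utci=utci,
        stress_category=StressCategory.MODERATE_HEAT)


def brute_force_extract(values, fraction, kind):
    """Independent nearest-rank reference: full sort, ties to earlier index."""
    n = len(values)
    k = math.ceil(fraction * n)
    sign = -1 if kind is ExtremeKind.HOT else 1
    ranked = sorted(range(n), key=lambda i: (sign * values[i], i))
    return sorted(ranked[:k])


def brute_force_single_linkage(chainages, gap):
    """Quadratic transitive-closure reference for 1-D single linkage."""
    n = len(chainages)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(chainages[i] - chainages[j]) <= gap:
                parent[find(i)] = find(j)
    groups: dict[int, list[float]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(chainages[i])
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestExtractExtremes:
    def test_single_hottest_record_at_five_percent_of_twenty(self):
        records = [_thermal(float(v), k) for k, v in enumerate(range(1, 21))]
        pts = extract_extremes(records, 0.05, ExtremeKind.HOT)
        assert len(pts) == 1 and pts[0].utci == 20.0

    def test_half_fraction_returns_exact_upper_half(self):
        values = [3.0, 9.0, 1.0, 7.0, 5.0, 8.0, 2.0, 6.0, 4.0, 0.0]
        records = [_thermal(v, k) for k, v in enumerate(values)]
        pts = extract_extremes(records, 0.5, ExtremeKind.HOT)
        assert sorted(p.utci for p in pts) == [5.0, 6.0, 7.0, 8.0, 9.0]

    def test_constant_lap_takes_earliest_records_with_warning(self):
        records = [_thermal(30.0, k) for k in range(10)]
        with pytest.warns(UserWarning, match="degenerate"):
            pts = extract_extremes(records, 0.3, ExtremeKind.HOT, lap_id="flat")
        assert [p.record.timestamp.second for p in pts] == [0, 1, 2]

    def test_cold_kind_selects_minima(self):
        records = [_thermal(float(v), k) for k, v in enumerate([5, 1, 4, 2, 3])]
        pts = extract_extremes(records, 0.4, ExtremeKind.COLD)
        assert sorted(p.utci for p in pts) == [1.0, 2.0]

    @pytest.mark.parametrize("fraction", [0.0, 0.51, 1.0, -0.1])
    def test_fraction_outside_contract_rejected(self, fraction):
        with pytest.raises(ValueError):
            extract_extremes([_thermal(1.0, 0)], fraction, ExtremeKind.HOT)

    def test_empty_lap_rejected(self):
        with pytest.raises(ValueError):
            extract_extremes([], 0.05, ExtremeKind.HOT)

    def test_count_law_and_disjointness_randomised(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(1, 120))
            values = rng.normal(30, 3, n)
            values += np.arange(n) * 1e-9  # make values distinct
            records = [_thermal(float(v), k) for k, v in enumerate(values)]
            frac = float(rng.uniform(0.01, 0.5))
            hot = extract_extremes(records, frac, ExtremeKind.HOT)
            cold = extract_extremes(records, frac, ExtremeKind.COLD)
            assert len(hot) == len(cold) == math.ceil(frac * n)
            if 2 * math.ceil(frac * n) <= n:
                assert not ({p.record.timestamp for p in hot}
                            & {p.record.timestamp for p in cold})
            # separation contract: worst selected beats best unselected
            chosen = {p.record.timestamp for p in hot}
            rest = [r.utci for r in records if r.timestamp not in chosen]
            if rest:
                assert min(p.utci for p in hot) >= max(rest)


def _straight_route():
    # ~1 km due-north line (geodesic length within 0.15% of 1001 m)
    return Route(lons=np.array([13.7320, 13.7320]),
                 lats=np.array([51.0400, 51.0490]))


def _pt(kind=ExtremeKind.HOT, session=Session.MIDDAY, chainage=0.0, utci=35.0, k=0):
    return ExtremePoint(record=_thermal(utci, k), kind=kind, lap_id="lap",
                        session=session, utci=utci, chainage_m=chainage)


class TestSnapToRoute:
    def test_point_on_vertex_snaps_to_vertex_chainage(self):
        route = _straight_route()
        p = ExtremePoint(record=_thermal(35.0, 0, lon=13.7320, lat=51.0400),
                         kind=ExtremeKind.HOT, lap_id="l", session=Session.MIDDAY,
                         utci=35.0)
        snapped, dropped = snap_to_route([p], route)
        assert not dropped
        assert snapped[0].chainage_m == pytest.approx(0.0, abs=0.01)

    def test_perpendicular_point_projects_to_foot(self):
        route = _straight_route()
        # a point at route midpoint, displaced ~5 m east (analytic projection:
        # chainage = half the route length, offset = displacement)
        lon_mid, lat_mid = route.point_at(route.length_m / 2)
        dlon = 5.0 / (111320.0 * math.cos(math.radians(lat_mid)))
        p = ExtremePoint(record=_thermal(35.0, 0, lon=lon_mid + dlon, lat=lat_mid),
                         kind=ExtremeKind.HOT, lap_id="l", session=Session.MIDDAY,
                         utci=35.0)
        snapped, _ = snap_to_route([p], route)
        assert snapped[0].chainage_m == pytest.approx(route.length_m / 2, abs=0.1)
        assert snapped[0].snap_offset_m == pytest.approx(5.0, abs=0.1)

    def test_far_point_dropped_and_counted(self):
        route = _straight_route()
        near = ExtremePoint(record=_thermal(35.0, 0, lon=13.7320, lat=51.0410),
                            kind=ExtremeKind.HOT, lap_id="l",
                            session=Session.MIDDAY, utci=35.0)
        far = ExtremePoint(record=_thermal(35.0, 1, lon=13.7390, lat=51.0410),
                           kind=ExtremeKind.HOT, lap_id="l",
                           session=Session.MIDDAY, utci=35.0)
        snapped, dropped = snap_to_route([near, far], route, snap_max_m=30.0)
        assert len(snapped) == 1 and len(dropped) == 1

    def test_all_points_dropped_is_an_error(self):
        route = _straight_route()
        far = ExtremePoint(record=_thermal(35.0, 0, lon=13.9, lat=51.2),
                           kind=ExtremeKind.HOT, lap_id="l",
                           session=Session.MIDDAY, utci=35.0)
        with pytest.raises(ValueError, match="route"):
            snap_to_route([far], route, snap_max_m=30.0)


class TestClusterSession:
    def test_four_nearby_points_form_one_cluster(self):
        pts = [_pt(chainage=c, k=i) for i, c in enumerate([10, 15, 20, 22])]
        clusters, omitted = cluster_session(pts, 25.0, 4)
        assert len(clusters) == 1 and not omitted
        assert clusters[0].interval == (10.0, 22.0)
        assert clusters[0].n_points == 4

    def test_small_groups_omitted(self):
        pts = [_pt(chainage=c, k=i) for i, c in enumerate([10, 15, 800])]
        clusters, omitted = cluster_session(pts, 25.0, 4)
        assert clusters == [] and len(omitted) == 3

    def test_empty_input_empty_output(self):
        assert cluster_session([], 25.0, 4) == ([], [])

    def test_cluster_statistics(self):
        pts = [_pt(chainage=c, utci=u, k=i)
               for i, (c, u) in enumerate([(0, 30.0), (10, 40.0), (20, 35.0),
                                           (30, 31.0)])]
        clusters, _ = cluster_session(pts, 25.0, 4)
        assert clusters[0].peak_utci == 40.0
        assert clusters[0].mean_utci == pytest.approx(34.0)

    def test_matches_brute_force_reference_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 200))
            chain = np.sort(rng.uniform(0, 3000, n))
            gap = float(rng.uniform(5, 100))
            pts = [_pt(chainage=float(c), k=i) for i, c in enumerate(chain)]
            clusters, omitted = cluster_session(pts, gap, min_cluster_points=1)
            got = sorted(tuple(p.chainage_m for p in c.points) for c in clusters)
            assert omitted == []
            assert got == brute_force_single_linkage(list(chain), gap)


class TestIntersectSessions:
    def _clusters(self, intervals_by_session, kind=ExtremeKind.HOT):
        out = {}
        for sess, intervals in intervals_by_session.items():
            cl = []
            for (a, b) in intervals:
                pts = tuple(_pt(kind=kind, session=sess, chainage=c, k=i)
                            for i, c in enumerate(np.linspace(a, b, 4)))
                cl.append(Cluster(kind=kind, session=sess, start_m=a, end_m=b,
                                  points=pts, mean_utci=35.0, peak_utci=36.0))
            out[sess] = cl
        return out

    def test_identical_clusters_roundtrip_through_buffering(self):
        cmap = self._clusters({s: [(100.0, 150.0)] for s in Session})
        zones = intersect_sessions(cmap, intersect_buffer_m=10.0)
        assert len(zones) == 1
        assert zones[0].interval == (100.0, 150.0)
        assert set(zones[0].contributing) == set(Session)

    def test_empty_session_means_no_zones(self):
        cmap = self._clusters({s: [(100.0, 150.0)] for s in Session})
        cmap[Session.EVENING] = []
        assert intersect_sessions(cmap) == []

    def test_four_interval_intersection_with_zero_buffer(self):
        intervals = {Session.MORNING: [(0.0, 100.0)],
                     Session.MIDDAY: [(50.0, 150.0)],
                     Session.AFTERNOON: [(80.0, 120.0)],
                     Session.EVENING: [(90.0, 200.0)]}
        zones = intersect_sessions(self._clusters(intervals), intersect_buffer_m=0.0)
        assert len(zones) == 1
        assert zones[0].interval == (90.0, 100.0)

    def test_buffer_bridges_small_session_drift(self):
        intervals = {Session.MORNING: [(100.0, 150.0)],
                     Session.MIDDAY: [(108.0, 158.0)],
                     Session.AFTERNOON: [(95.0, 145.0)],
                     Session.EVENING: [(104.0, 154.0)]}
        strict = intersect_sessions(self._clusters(intervals), 0.0)
        buffered = intersect_sessions(self._clusters(intervals), 10.0)
        assert strict[0].interval == (108.0, 145.0)
        # dilate-intersect-erode recovers the drift without inflating the zone
        assert buffered[0].interval == (108.0, 145.0)

    def test_gap_beyond_buffer_yields_nothing(self):
        intervals = {Session.MORNING: [(0.0, 50.0)],
                     Session.MIDDAY: [(80.0, 120.0)],
                     Session.AFTERNOON: [(0.0, 50.0)],
                     Session.EVENING: [(0.0, 50.0)]}
        assert intersect_sessions(self._clusters(intervals), 10.0) == []

    def test_missing_session_key_is_an_error(self):
        cmap = self._clusters({Session.MORNING: [(0.0, 10.0)]})
        with pytest.raises(ValueError, match="missing"):
            intersect_sessions(cmap)

    def test_zone_subset_of_contributing_buffered_intervals(self):
        intervals = {Session.MORNING: [(0.0, 100.0), (300.0, 400.0)],
                     Session.MIDDAY: [(50.0, 150.0), (290.0, 380.0)],
                     Session.AFTERNOON: [(80.0, 120.0), (310.0, 420.0)],
                     Session.EVENING: [(90.0, 200.0), (305.0, 390.0)]}
        buffer_m = 10.0
        zones = intersect_sessions(self._clusters(intervals), buffer_m)
        assert len(zones) == 2
        for z in zones:
            for sess, cl in z.contributing.items():
                assert cl.start_m - buffer_m <= z.start_m
                assert z.end_m <= cl.end_m + buffer_m


class TestThresholdConfig:
    def test_defaults_follow_field_protocol(self):
        cfg = ThresholdConfig()
        assert cfg.fraction == 0.05 and cfg.min_cluster_points == 4

    @pytest.mark.parametrize("kw", [{"fraction": 1.0}, {"fraction": 0.0},
                                    {"min_cluster_points": 0},
                                    {"cluster_gap_m": -5.0}])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            ThresholdConfig(**kw)


class TestRunPrioritisation:
    def test_deterministic_and_idempotent(self, demo_enriched):
        enriched, route = demo_enriched
        r1 = run_prioritisation(enriched, route)
        r2 = run_prioritisation(enriched, route)
        assert [z.interval for z in r1.hot_zones] == [z.interval for z in r2.hot_zones]
        assert [z.interval for z in r1.cold_zones] == [z.interval for z in r2.cold_zones]
        assert r1.qc == r2.qc

    def test_missing_session_warns_and_skips_intersection(self, demo_enriched):
        enriched, route = demo_enriched
        partial = {k: v for k, v in enriched.items() if k[1] is not Session.EVENING}
        with pytest.warns(UserWarning, match="lacks sessions"):
            res = run_prioritisation(partial, route)
        assert res.hot_zones == [] and res.cold_zones == []
        assert res.qc["missing_sessions"] == ["EVENING"]
        # per-session clusters for the present sessions are still produced
        assert any(res.clusters[ExtremeKind.HOT][s] for s in Session
                   if s is not Session.EVENING)

    def test_empty_input_rejected(self, demo_enriched):
        _, route = demo_enriched
        with pytest.raises(ValueError):
            run_prioritisation({}, route)

    def test_recovers_planted_zones_in_demo_campaign(self, demo_scenario,
                                                     demo_enriched):
        enriched, route = demo_enriched
        res = run_prioritisation(enriched, route)
        gt = sd.ground_truth(demo_scenario)
        j_hot = sd.recovery_jaccard([z.interval for z in res.hot_zones],
                                    gt.consistent_hot)
        j_cold = sd.recovery_jaccard([z.interval for z in res.cold_zones],
                                     gt.consistent_cold)
        assert j_hot > 0.7 and j_cold > 0.7
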