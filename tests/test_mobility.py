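"""Home anchor, loop detection (with brute-force oracle), visits and
categorisation."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import commpart as cp
import commpart.mobility as mob
from commpart.geo import LocalFrame, haversine_m
from commpart.types import GpsTrack, HomeAnchor, LocationVisit, TripEpisode

FRAME = LocalFrame(-35.0, 138.6)
START = np.datetime64("2019-03-04T00:00:00")


def _track_from_xy(xy: list, epoch=5, start=START, pid="P001") -> GpsTrack:
    xy = np.asarray(xy, float)
    lat, lon = FRAME.to_latlon(xy[:, 0], xy[:, 1])
    ts = start + (np.arange(len(xy)) * epoch).astype("timedelta64[s]")
    return GpsTrack(pid, ts, lat, lon, epoch)


def _track_from_membership(seq, far=500.0) -> GpsTrack:
    """inside=True fixes at the origin, outside fixes 500 m east."""
    xy = [(0.0, 0.0) if s else (far, 0.0) for s in seq]
    return _track_from_xy(xy)


HOME = HomeAnchor(-35.0, 138.6, 100.0)


# --------------------------------------------------------------------------
# Home estimation
# --------------------------------------------------------------------------


def test_home_at_single_nocturnal_point():
    n = 1000
    ts = START + (np.arange(n) * 5).astype("timedelta64[s]")  # 00:00-01:23
    track = GpsTrack("P", ts, np.full(n, -35.01), np.full(n, 138.61), 5)
    anchor = mob.estimate_home(track)
    assert haversine_m(anchor.lat, anchor.lon, -35.01, 138.61) < 1.0


def test_home_recovered_on_synthetic_cohort(clean_cohort_small):
    bundles, truth, _ = clean_cohort_small
    for b in bundles:
        t = truth.participants[b.participant_id]
        anchor = mob.estimate_home(b.gps)
        assert haversine_m(anchor.lat, anchor.lon, t.home_lat, t.home_lon) < 50


def test_equal_clusters_break_southwest():
    # two equally dense nocturnal clusters 1 km apart on the x axis
    a = [(0.0, 0.0)] * 50
    b = [(1000.0, 0.0)] * 50
    track = _track_from_xy(a + b)
    anchor = mob.estimate_home(track)
    assert haversine_m(anchor.lat, anchor.lon, -35.0, 138.6) < 5.0  # west one


def test_no_nocturnal_fixes_requires_explicit_home():
    ts = np.datetime64("2019-03-04T12:00:00") + (
        np.arange(10) * 5
    ).astype("timedelta64[s]")
    track = GpsTrack("P", ts, np.full(10, -35.0), np.full(10, 138.6), 5)
    with pytest.raises(ValueError, match="explicit home"):
        mob.estimate_home(track)


# --------------------------------------------------------------------------
# Trip detection
# --------------------------------------------------------------------------


def test_all_fixes_at_home_zero_trips():
    track = _track_from_membership([True] * 200)
    assert mob.detect_trips(track, HOME) == []


def test_empty_track_empty_list():
    track = GpsTrack("P", np.array([], dtype="datetime64[s]"),
                     np.array([]), np.array([]), 5)
    assert mob.detect_trips(track, HOME) == []


def _oracle_trip_indices(seq):
    """Independent per-index scan of the home-membership sequence."""
    trips, out, start = [], False, None
    n = len(seq)
    for i in range(n):
        if not out:
            if not seq[i] and i + 1 < n and not seq[i + 1]:
                out, start = True, i
        else:
            if seq[i] and i + 1 < n and seq[i + 1]:
                trips.append((start, i, True))
                out = False
    if out:
        trips.append((start, n - 1, False))
    return trips


@given(st.lists(st.booleans(), min_size=2, max_size=1000))
def test_detection_matches_bruteforce_scan(seq):
    track = _track_from_membership(seq)
    got = mob.detect_trips(track, HOME, min_trip_min=0.0, bridge_gap_min=60.0)
    want = _oracle_trip_indices(seq)
    assert len(got) == len(want)
    for trip, (s, e, complete) in zip(got, want):
        assert trip.departure == track.timestamps[s]
        assert trip.complete_loop == complete
        if complete:
            assert trip.return_ == track.timestamps[e]


def test_short_episodes_discarded():
    # 6 fixes outside = 30 s episode, below a 5-min minimum
    seq = [True] * 10 + [False] * 6 + [True] * 10
    track = _track_from_membership(seq)
    assert mob.detect_trips(track, HOME, min_trip_min=5.0) == []
    assert len(mob.detect_trips(track, HOME, min_trip_min=0.0)) == 1


def test_scheduled_loops_recovered_with_epoch_accuracy(clean_cohort_small):
    """Detected departures/returns sit within one epoch of the home-radius
    crossing recorded in the ground truth."""
    bundles, truth, _ = clean_cohort_small
    b = bundles[1]
    t = truth.participants[b.participant_id]
    home = HomeAnchor(t.home_lat, t.home_lon, 100.0)
    trips = mob.detect_trips(b.gps, home)
    assert len(trips) == len(t.trips)
    eps = np.timedelta64(3 * 5, "s")  # jitter can shift the crossing a little
    for det, tru in zip(trips, t.trips):
        assert abs(det.departure - tru.t_exit) <= eps
        assert abs(det.return_ - tru.t_enter) <= eps


def test_long_gap_resuming_at_home_closes_loop():
    seq_out = [False] * 240  # 20 min outside
    track = _track_from_membership([True] * 10 + seq_out + [True] * 10)
    # remove the last 180 outside fixes -> 15-min gap, resumes at home
    keep = np.ones(track.n_fixes, bool)
    keep[10 + 60: 10 + 240] = False
    gappy = GpsTrack("P", track.timestamps[keep], track.lat[keep],
                     track.lon[keep], 5)
    trips = mob.detect_trips(gappy, HOME, min_trip_min=0.0, bridge_gap_min=10.0)
    assert len(trips) == 1
    assert trips[0].complete_loop
    assert trips[0].return_ == gappy.timestamps[10 + 60 - 1]  # last out fix


def test_loss_covering_trip_hides_exactly_that_trip(clean_cohort_small):
    bundles, truth, _ = clean_cohort_small
    b = bundles[2]
    t = truth.participants[b.participant_id]
    victim = t.trips[1]
    pad = np.timedelta64(120, "s")
    keep = ~(
        (b.gps.timestamps >= victim.departure - pad)
        & (b.gps.timestamps <= victim.return_ + pad)
    )
    gappy = GpsTrack(b.participant_id, b.gps.timestamps[keep],
                     b.gps.lat[keep], b.gps.lon[keep], 5)
    home = HomeAnchor(t.home_lat, t.home_lon, 100.0)
    trips = mob.detect_trips(gappy, home)
    assert len(trips) == len(t.trips) - 1
    # the surviving departures correspond to every trip except the victim
    for tru in t.trips:
        hit = any(abs(d.departure - tru.t_exit) <= np.timedelta64(30, "s")
                  for d in trips)
        assert hit == (tru is not victim)


def test_trips_disjoint_and_ordered(run44_clean):
    result, _ = run44_clean
    for r in result.participants.values():
        for a, b in zip(r.trips[:-1], r.trips[1:]):
            assert a.return_ <= b.departure


# --------------------------------------------------------------------------
# Visits
# --------------------------------------------------------------------------


def _stop_trip_track(stops, dwell_fixes=400, travel_step=40.0):
    """Home -> dwell at each stop -> home, 5-s epochs, with tiny jitter."""
    rng = np.random.default_rng(0)
    xy = [(0.0, 0.0)] * 10
    pos = np.array([0.0, 0.0])
    for stop in stops:
        stop = np.asarray(stop, float)
        while np.linalg.norm(stop - pos) > travel_step:
            pos = pos + (stop - pos) / np.linalg.norm(stop - pos) * travel_step
            xy.append(tuple(pos))
        xy.extend([tuple(stop + rng.normal(0, 2, 2)) for _ in range(dwell_fixes)])
        pos = stop
    while np.linalg.norm(pos) > travel_step:
        pos = pos - pos / np.linalg.norm(pos) * travel_step
        xy.append(tuple(pos))
    xy.extend([(0.0, 0.0)] * 10)
    return _track_from_xy(xy)


def test_single_stop_yields_one_visit():
    track = _stop_trip_track([(800.0, 0.0)])
    trips = mob.detect_trips(track, HOME)
    assert len(trips) == 1
    visits = mob.detect_visits(trips[0], track)
    assert len(visits) == 1
    assert visits[0].dwell_min >= 30


def test_continuous_driving_yields_no_visits():
    # out 2 km and straight back at 40 m per fix, never stationary
    out = [(40.0 * k, 0.0) for k in range(1, 51)]
    back = list(reversed(out))
    track = _track_from_xy([(0.0, 0.0)] * 10 + out + back + [(0.0, 0.0)] * 10)
    trips = mob.detect_trips(track, HOME, min_trip_min=0.0)
    assert len(trips) == 1
    assert mob.detect_visits(trips[0], track) == []


def test_two_stops_400m_apart_give_two_visits():
    track = _stop_trip_track([(800.0, 0.0), (800.0, 400.0)])
    trips = mob.detect_trips(track, HOME)
    visits = mob.detect_visits(trips[0], track)
    assert len(visits) == 2
    d = haversine_m(visits[0].lat, visits[0].lon, visits[1].lat, visits[1].lon)
    assert 300 < d < 500


# --------------------------------------------------------------------------
# Categorisation
# --------------------------------------------------------------------------


def _visit_at(lat, lon):
    return LocationVisit(START, START + np.timedelta64(600, "s"), lat, lon)


def test_centroid_at_fence_center():
    gaz = cp.build_gazetteer()
    f = gaz.features[0]
    v = mob.categorize_visit(_visit_at(f.lat, f.lon), gaz)
    assert v.category == f.category


def test_overlapping_fences_nearer_center_wins_and_tie_breaks():
    mk = lambda name, cat, dx: cp.GeoFence(
        name, *FRAME.to_latlon(dx, 0.0), 200.0, cat
    )
    gaz = cp.Gazetteer([mk("a", "commercial", 0.0), mk("b", "health", 100.0)])
    lat, lon = FRAME.to_latlon(20.0, 0.0)
    assert mob.categorize_visit(_visit_at(lat, lon), gaz).category == "commercial"
    # exact tie at the midpoint: listing order prefers health over cbd
    gaz2 = cp.Gazetteer([mk("a", "cbd", 0.0), mk("b", "health", 100.0)])
    lat, lon = FRAME.to_latlon(50.0, 0.0)
    assert mob.categorize_visit(_visit_at(lat, lon), gaz2).category == "health"


def test_snap_within_tolerance_else_unknown():
    gaz = cp.build_gazetteer()
    f = gaz.features[0]
    frame = LocalFrame(f.lat, f.lon)
    lat, lon = frame.to_latlon(f.radius_m + 50.0, 0.0)
    assert mob.categorize_visit(_visit_at(lat, lon), gaz,
                                max_snap_m=100).category == f.category
    lat, lon = frame.to_latlon(f.radius_m + 160.0, 0.0)
    assert mob.categorize_visit(_visit_at(lat, lon), gaz,
                                max_snap_m=100).category == "unknown"


def test_cohort_visit_categories_match_truth(clean_cohort_small,
                                             clean_run_small):
    result, truth = clean_run_small
    match = total = 0
    for pid, r in result.participants.items():
        det = sorted(v.category for t in r.trips for v in t.visits)
        tru = sorted(v.category for t in truth.participants[pid].trips
                     for v in t.visits)
        total += len(tru)
        match += sum(a == b for a, b in zip(det, tru)) if det == tru else 0
    assert total > 0 and match / total >= 0.95


# --------------------------------------------------------------------------
# Walk loops and participation counts
# --------------------------------------------------------------------------


def test_visitless_neighbourhood_loop_is_local_walk():
    out = [(7.0 * k, 0.0) for k in range(1, 101)]  # walk 700 m out
    track = _track_from_xy([(0.0, 0.0)] * 10 + out + list(reversed(out))
                           + [(0.0, 0.0)] * 10)
    trips = mob.detect_trips(track, HOME, min_trip_min=0.0)
    assert len(trips) == 1
    trips[0].visits = mob.detect_visits(trips[0], track)
    assert trips[0].visits == []
    assert mob.classify_walk_loop(trips[0], track, HOME)
    trips[0].walk_loop = True
    counts = mob.count_participation(trips)
    assert counts["visits_by_category"]["local_walk_greenspace"] == 1


def test_zero_trips_zero_counts():
    counts = mob.count_participation([])
    assert counts["trips_total"] == 0
    assert all(v == 0 for v in counts["visits_by_category"].values())


def test_category_counts_not_bounded_by_trip_count():
    """A single trip with several visits exceeds the trip count; a visit-less
    trip contributes none — no sum constraint holds."""
    v1 = _visit_at(-35.0, 138.6)
    v1.category = "commercial"
    v2 = _visit_at(-35.0, 138.6)
    v2.category = "commercial"
    multi = TripEpisode(START, START + np.timedelta64(3600, "s"),
                        visits=[v1, v2])
    bare = TripEpisode(START, START + np.timedelta64(7200, "s"))
    counts = mob.count_participation([multi, bare])
    assert counts["trips_total"] == 2
    assert counts["visits_by_category"]["commercial"] == 2


def test_commercial_is_modal_category(run44_clean):
    result, _ = run44_clean
    totals = {c: 0 for c in cp.CATEGORIES}
    for _, row in result.summaries.iterrows():
        for c in cp.CATEGORIES:
            totals[c] += row[f"visits_{c}"]
    assert max(totals, key=totals.get) == "commercial"


def test_gps_validity_gate():
    report = cp.compute_data_loss(
        _track_from_membership([True] * 100), 7, START
    )
    ok, n_valid = mob.assess_gps_validity(report)
    assert not ok and n_valid == 0
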