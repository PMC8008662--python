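"""Generator contract: determinism, distribution targets, truth integrity."""
from __future__ import annotations

import numpy as np
import pytest
from pydantic import ValidationError

import commpart as cp
from commpart.geo import haversine_m
from commpart.synthetic_data import (
    TrueTrip,
    TrueVisit,
    _home_sites,
    build_gazetteer,
    emit_accel_series,
)
from commpart.types import CATEGORIES, LIGHT, MODERATE, SEDENTARY, SLEEP, VIGOROUS

from conftest import true_mvpa_minutes


# --------------------------------------------------------------------------
# Profile validation
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        {"category_visit_weights": {"commercial": 0.5}},  # does not sum to 1
        {"category_visit_weights": {"bowling": 1.0}},  # unknown category
        {"sleep_min_per_night": -1.0},
        {"days": 0},
        {"gps_epoch_s": 7},  # neither divides 60 nor multiple of it
        {"trips_per_week_iqr": (12.0, 9.0)},
    ],
)
def test_invalid_profiles_rejected(kwargs):
    with pytest.raises(ValidationError):
        cp.SimProfile(**kwargs)


def test_counts_forced_by_profile(clean_cohort_small, clean_profile_small):
    bundles, truth, gaz = clean_cohort_small
    assert len(bundles) == clean_profile_small.n_participants
    for b in bundles:
        assert b.gps.n_fixes == 7 * 86400 // 5  # loss-free: full grid
        assert b.accel.n_epochs == 7 * 86400 // 5
        assert b.diary is not None and len(b.diary) > 0
        assert set(b.covariates) >= {"hrqol", "loneliness", "sleep_quality"}


def test_degenerate_weights_give_single_category():
    w = {c: 0.0 for c in CATEGORIES}
    w["commercial"] = 1.0
    prof = cp.SimProfile(n_participants=1, days=7, seed=3,
                         category_visit_weights=w, gps_loss_hours_mean=0)
    _, truth, _ = cp.generate_cohort(prof)
    visits = [v for t in truth.participants["P001"].trips for v in t.visits]
    assert visits and all(v.category == "commercial" for v in visits)


def test_determinism_byte_identical():
    prof = cp.SimProfile(n_participants=2, days=2, seed=42)
    b1, t1, _ = cp.generate_cohort(prof)
    b2, t2, _ = cp.generate_cohort(prof)
    for a, b in zip(b1, b2):
        assert np.array_equal(a.gps.timestamps, b.gps.timestamps)
        assert np.array_equal(a.gps.lat, b.gps.lat)
        assert np.array_equal(a.accel.counts, b.accel.counts)
        assert [(e.start, e.activity) for e in a.diary] == [
            (e.start, e.activity) for e in b.diary
        ]
    for pid in t1.participants:
        assert np.array_equal(
            t1.participants[pid].minute_classes, t2.participants[pid].minute_classes
        )


def test_cohort_trip_median_matches_profile(cohort200):
    """Oracle: trips counted directly from the ground-truth schedules."""
    _, truth, _ = cohort200
    weekly = [len(t.trips) for t in truth.participants.values()]
    assert 13 <= np.median(weekly) <= 17


def test_cohort_mvpa_median_matches_profile(cohort200):
    _, truth, _ = cohort200
    mvpa = [true_mvpa_minutes(t) / t.days for t in truth.participants.values()]
    assert 60 <= np.median(mvpa) <= 74


def test_minute_classes_partition_full_span(clean_cohort_small):
    """Sleep plus the four waking classes tile 24 h x days exactly."""
    _, truth, _ = clean_cohort_small
    for t in truth.participants.values():
        cls = t.minute_classes
        assert cls.size == t.days * 1440
        n = sum(
            int(np.sum(cls == c))
            for c in (SLEEP, SEDENTARY, LIGHT, MODERATE, VIGOROUS)
        )
        assert n == cls.size


def test_trips_are_non_overlapping_loops(clean_cohort_small):
    _, truth, _ = clean_cohort_small
    for t in truth.participants.values():
        trips = sorted(t.trips, key=lambda x: x.departure)
        for a, b in zip(trips[:-1], trips[1:]):
            assert a.return_ <= b.departure
        for tr in trips:
            assert tr.departure < tr.return_


def test_every_visit_inside_exactly_one_geofence(clean_cohort_small):
    _, truth, gaz = clean_cohort_small
    for t in truth.participants.values():
        for tr in t.trips:
            for v in tr.visits:
                containing = [
                    f for f in gaz.features
                    if haversine_m(v.lat, v.lon, f.lat, f.lon) <= f.radius_m
                ]
                assert len(containing) == 1
                assert containing[0].category == v.category


def test_home_sites_clear_of_fences():
    sites = _home_sites(200)
    gaz = build_gazetteer()
    from commpart.geo import LocalFrame
    from commpart.synthetic_data import TOWN_CENTER

    frame = LocalFrame(*TOWN_CENTER)
    for x, y in sites:
        lat, lon = frame.to_latlon(x, y)
        for f in gaz.features:
            assert haversine_m(lat, lon, f.lat, f.lon) > 400


# --------------------------------------------------------------------------
# GPS emission
# --------------------------------------------------------------------------


def test_empty_schedule_stays_at_home():
    gaz = build_gazetteer()
    home = (-35.003, 138.57)
    track = cp.emit_gps_track([], home, gaz, 5, seed=0, days=1)
    d = haversine_m(track.lat, track.lon, home[0], home[1])
    assert track.n_fixes == 86400 // 5
    assert np.max(d) < 50  # within jitter of the home point


def test_trip_fixes_inside_destination_geofence(clean_cohort_small):
    bundles, truth, gaz = clean_cohort_small
    b = bundles[0]
    t = truth.participants[b.participant_id]
    trip = next(tr for tr in t.trips if tr.visits)
    v = trip.visits[0]
    fence = next(f for f in gaz.features if f.name == v.fence)
    # fixes strictly inside the dwell (10 min buffer) sit inside the fence
    m = (
        (b.gps.timestamps >= v.arrival + np.timedelta64(60, "s"))
        & (b.gps.timestamps < v.departure - np.timedelta64(60, "s"))
    )
    d = haversine_m(b.gps.lat[m], b.gps.lon[m], fence.lat, fence.lon)
    assert m.sum() > 0 and np.max(d) <= fence.radius_m


def test_unknown_visit_category_fails():
    gaz = cp.Gazetteer([f for f in build_gazetteer().features
                        if f.category != "health"])
    s = np.datetime64("2019-03-04T10:00:00")
    v = TrueVisit("health", "gp_clinic", s + np.timedelta64(600, "s"),
                  s + np.timedelta64(2400, "s"), -35.0, 138.6)
    trip = TrueTrip(s, s + np.timedelta64(3000, "s"), [v], "vehicle", s, s)
    with pytest.raises(ValueError, match="absent from gazetteer"):
        cp.emit_gps_track([trip], (-35.0, 138.58), gaz, 5, seed=0, days=1)


# --------------------------------------------------------------------------
# Signal loss
# --------------------------------------------------------------------------


def test_zero_loss_is_noop():
    gaz = build_gazetteer()
    track = cp.emit_gps_track([], (-35.0, 138.58), gaz, 5, seed=1, days=1)
    out = cp.inject_signal_loss(track, 0.0, seed=2)
    assert out.n_fixes == track.n_fixes
    assert out.resume_points.size == 0


def test_loss_hours_accounting():
    """Removed-fix count x epoch / 3600 reproduces the requested loss."""
    gaz = build_gazetteer()
    track = cp.emit_gps_track([], (-35.0, 138.58), gaz, 5, seed=1, days=7)
    out = cp.inject_signal_loss(track, 9.3, seed=3)
    removed_h = (track.n_fixes - out.n_fixes) * 5 / 3600.0
    assert abs(removed_h - 9.3) <= 5 / 3600.0
    assert out.resume_points.size >= 1


def test_negative_loss_rejected():
    gaz = build_gazetteer()
    track = cp.emit_gps_track([], (-35.0, 138.58), gaz, 5, seed=1, days=1)
    with pytest.raises(ValueError):
        cp.inject_signal_loss(track, -1.0, seed=0)


# --------------------------------------------------------------------------
# Accelerometer emission
# --------------------------------------------------------------------------


def test_accel_counts_recover_truth_classes(clean_cohort_small):
    """Classification at 60 s must reproduce the minute-class ground truth."""
    import commpart.accel_metrics as am

    _, truth, _ = clean_cohort_small
    t = next(iter(truth.participants.values()))
    series = emit_accel_series(t, 5, seed=9)
    agg = am.aggregate_epochs(series, 60)
    classified = am.classify_intensity(agg, am.CutPoints())
    # sleep minutes classify as sedentary until masked; compare waking only
    waking = t.minute_classes != SLEEP
    assert np.array_equal(
        classified.classes[waking], t.minute_classes[waking]
    )


# --------------------------------------------------------------------------
# Diary emission
# --------------------------------------------------------------------------


def test_diary_counts_match_truth_without_overreporting(clean_cohort_small):
    from commpart.fusion_diary import diary_trips

    bundles, truth, _ = clean_cohort_small
    for b in bundles:
        t = truth.participants[b.participant_id]
        assert len(diary_trips(b.diary)) == len(t.trips)


def test_overreporting_rate_close_to_target():
    """Cohort mean diary-minus-true trips approaches the phantom rate."""
    from commpart.fusion_diary import diary_trips

    prof = cp.SimProfile(n_participants=30, days=7, seed=13,
                         gps_loss_hours_mean=0.0, diary_overreport_rate=1.3,
                         diary_jitter_min=0.0)
    bundles, truth, _ = cp.generate_cohort(prof)
    diffs = [
        len(diary_trips(b.diary)) - len(truth.participants[b.participant_id].trips)
        for b in bundles
    ]
    assert all(d >= 0 for d in diffs)
    assert 0.7 <= np.mean(diffs) <= 1.9


def test_jitter_beyond_tolerance_leaves_unmatched():
    """Exhaustive windowed matching: +/-15 min jitter vs 10 min tolerance."""
    from commpart.fusion_diary import diary_trips, match_diary_to_gps
    from commpart.types import TripEpisode

    prof = cp.SimProfile(n_participants=4, days=7, seed=17,
                         gps_loss_hours_mean=0.0, diary_overreport_rate=0.0,
                         diary_jitter_min=15.0)
    bundles, truth, _ = cp.generate_cohort(prof)
    unmatched = 0
    for b in bundles:
        t = truth.participants[b.participant_id]
        gps = [TripEpisode(tr.departure, tr.return_) for tr in t.trips]
        res = match_diary_to_gps(diary_trips(b.diary), gps, tolerance_min=10.0)
        unmatched += res.unmatched_diary
    assert unmatched > 0
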