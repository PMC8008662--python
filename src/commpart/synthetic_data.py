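"""Ground-truthed synthetic cohorts of GPS, accelerometer and diary data.

The generator emulates a 7-day free-living monitoring protocol in
community-dwelling older adults: a waist/lanyard GPS logger at 5-s epochs, a
continuously-worn wrist accelerometer summarised as counts per epoch, and a
self-completed activity diary.  Its defaults reproduce the cohort structure
the pipeline is designed to measure:

* median 15 (IQR 9.25-18.75) out-of-home trips per 7 days,
* ~67 min/day moderate-to-vigorous physical activity (MVPA),
* ~659 min/day sedentary time and ~480 min/night sleep,
* mean 9.3 h of GPS signal loss per 7 days, and
* diary over-reporting of ~1.3 trips/week, concentrated on commercial and
  recreational destinations.

Every participant carries a full :class:`ParticipantTruth` record (trip
schedule, per-minute intensity class, sleep windows, per-visit social
interactions) against which pipeline recovery is scored.

Geography is a flat synthetic town on real coordinates near (-35.0, 138.6)
with circular geofences >= 300 m apart, so every visit lies inside exactly
one fence and categorisation is unambiguous.  Trip schedules are built on a
whole-minute grid; GPS fixes interpolate straight lines between the home and
geofence stop points at constant speed (walking 1.4 m/s for local
walk/greenspace loops, 8 m/s otherwise).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.special import ndtr, ndtri

from .geo import LocalFrame, haversine_m
from .types import (
    CATEGORIES,
    LIGHT,
    MODERATE,
    SEDENTARY,
    SLEEP,
    VIGOROUS,
    DiaryEntry,
    EpochSeries,
    Gazetteer,
    GeoFence,
    GpsTrack,
    ParticipantBundle,
    as_dt64,
    floor_day,
)

# --------------------------------------------------------------------------
# Town geography
# --------------------------------------------------------------------------

TOWN_CENTER = (-35.0, 138.6)  # Adelaide-like latitude/longitude

#: (name, category, x_east_m, y_north_m, radius_m); all centres >= 300 m apart.
_FENCES_XY = (
    ("commercial_mall", "commercial", 800.0, 0.0, 120.0),
    ("commercial_shops", "commercial", 1600.0, 900.0, 100.0),
    ("recreation_centre", "recreational", 400.0, 900.0, 110.0),
    ("swimming_pool", "recreational", 1400.0, -700.0, 100.0),
    ("friends_house_a", "residential", 200.0, -800.0, 90.0),
    ("friends_house_b", "residential", 1000.0, 1500.0, 90.0),
    ("gp_clinic", "health", 1800.0, 200.0, 90.0),
    ("cbd_precinct", "cbd", 2600.0, 0.0, 150.0),
    ("church", "place_of_worship", 600.0, 1600.0, 80.0),
    ("park_north", "local_walk_greenspace", -1500.0, 900.0, 120.0),
    ("park_south", "local_walk_greenspace", -2400.0, -700.0, 120.0),
    ("beach_walk", "local_walk_greenspace", -3300.0, 400.0, 110.0),
)

WALK_SPEED_MS = 1.4
VEHICLE_SPEED_MS = 8.0
HOME_JITTER_SD_M = 5.0
STOP_JITTER_SD_M = 5.0
HOME_REFERENCE_RADIUS_M = 100.0  # radius used when recording truth exit/entry times

#: Category visit weights ~ proportional to the weekly GPS visit means the
#: protocol is calibrated to (residential 2.5, recreational 4.9, commercial
#: 5.6, health 0.7, local walk 3.6, CBD 1.7, worship 0.3).
_DEFAULT_WEIGHTS = {
    "residential": 2.5 / 19.3,
    "recreational": 4.9 / 19.3,
    "commercial": 5.6 / 19.3,
    "health": 0.7 / 19.3,
    "local_walk_greenspace": 3.6 / 19.3,
    "cbd": 1.7 / 19.3,
    "place_of_worship": 0.3 / 19.3,
}

#: Dwell-time ranges (whole minutes) by destination category.
_DWELL_RANGE = {
    "residential": (45, 120),
    "recreational": (40, 90),
    "commercial": (20, 60),
    "health": (20, 60),
    "local_walk_greenspace": (25, 50),
    "cbd": (40, 120),
    "place_of_worship": (45, 90),
}

#: Mean social interactions per visit by category.  Only residential,
#: recreational and commercial venues generate interactions, mirroring the
#: reporting pattern the cohort statistics are anchored to (recreational and
#: commercial the modal venues; weekly out-of-home total ~11.5).
_SOCIAL_MEAN = {
    "residential": 1.25,
    "recreational": 1.25,
    "commercial": 0.95,
    "health": 0.0,
    "local_walk_greenspace": 0.0,
    "cbd": 0.0,
    "place_of_worship": 0.0,
}

#: Where diary phantom (over-reported) trips go: the over-report bias is
#: concentrated on commercial (0.7/wk) and recreational (0.6/wk) venues.
_PHANTOM_WEIGHTS = {"commercial": 0.7 / 1.3, "recreational": 0.6 / 1.3}

_ACTIVITY_TEXT = {
    "residential": "visiting friends",
    "recreational": "class at the recreation centre",
    "commercial": "shopping at the local shops",
    "health": "GP appointment",
    "local_walk_greenspace": "walk in the park",
    "cbd": "errands in the city",
    "place_of_worship": "service at church",
}
_HOME_ACTIVITIES = (
    "reading the paper",
    "watching television",
    "computer work",
    "listening to the radio",
    "gardening",
)

#: Mean MVPA minutes contributed by one local-walk trip (dwell plus walking
#: travel, minus the light-intensity edge minutes) under the default town
#: layout.  Used only to centre the at-home MVPA baseline so the cohort
#: median lands on the profile target.
_MEAN_WALK_TRIP_MVPA_MIN = 68.0
#: Minutes contributed per walk trip to the MVPA coupling are large by
#: construction; minutes of extra at-home MVPA day-to-day noise:
_MVPA_DAY_SD = 10.0
_MVPA_PARTICIPANT_SD = 12.0

# Mondays keep simulated days 6-7 on Saturday/Sunday.
_DEFAULT_START = "2019-03-04T00:00:00"


# --------------------------------------------------------------------------
# Profile and ground truth
# --------------------------------------------------------------------------


class SimProfile(BaseModel):
    """Cohort-level simulation parameters (the study conditions)."""

    n_participants: int = Field(44, ge=1)
    days: int = Field(7, ge=1)
    gps_epoch_s: int = Field(5, gt=0)
    accel_epoch_s: int = Field(5, gt=0)
    trips_per_week_median: float = Field(15.0, ge=0)
    trips_per_week_iqr: tuple[float, float] = (9.25, 18.75)
    category_visit_weights: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    mvpa_min_per_day: float = Field(67.0, ge=0)
    sedentary_min_per_day: float = Field(659.0, ge=0)
    sedentary_sd_min: float = Field(91.0, ge=0)
    sleep_min_per_night: float = Field(480.0, ge=0)
    sleep_sd_min: float = Field(58.0, ge=0)
    gps_loss_hours_mean: float = Field(9.3, ge=0)
    diary_overreport_rate: float = Field(1.3, ge=0)  # phantom trips per week
    diary_jitter_min: float = Field(5.0, ge=0)
    #: probability that a vehicle outing chains a second distinct stop.
    #: Default 0: single-destination loops keep diary location reports and
    #: GPS visit counts commensurable (the pipeline itself handles
    #: multi-visit trips regardless).
    two_stop_prob: float = Field(0.0, ge=0, le=1)
    monitoring_start: str = _DEFAULT_START
    #: participant indices (0-based) whose accelerometer malfunctions / whose
    #: diary is never returned — used to exercise the exclusion gate.
    accel_malfunction_ids: tuple[int, ...] = ()
    missing_diary_ids: tuple[int, ...] = ()
    seed: int = 0

    @field_validator("gps_epoch_s", "accel_epoch_s")
    @classmethod
    def _epoch_compatible(cls, v: int) -> int:
        if not (60 % v == 0 or v % 60 == 0):
            raise ValueError("epoch length must divide 60 s or be a multiple of it")
        return v

    @field_validator("category_visit_weights")
    @classmethod
    def _weights_valid(cls, w: dict) -> dict:
        unknown = set(w) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in weights: {sorted(unknown)}")
        if any(p < 0 for p in w.values()):
            raise ValueError("category weights must be non-negative")
        total = sum(w.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"category weights must sum to 1 (got {total:.6f})")
        return w

    @model_validator(mode="after")
    def _iqr_ordered(self):
        lo, hi = self.trips_per_week_iqr
        if not (0 <= lo <= hi):
            raise ValueError("trips_per_week_iqr must satisfy 0 <= q1 <= q3")
        return self

    def weight_vector(self) -> np.ndarray:
        return np.array([self.category_visit_weights.get(c, 0.0) for c in CATEGORIES])


@dataclass
class TrueVisit:
    category: str
    fence: str
    arrival: np.datetime64  # whole-minute grid
    departure: np.datetime64
    lat: float
    lon: float  # stop point inside the fence
    social_interactions: int = 0


@dataclass
class TrueTrip:
    departure: np.datetime64
    return_: np.datetime64
    visits: list[TrueVisit]
    mode: str  # "walk" | "vehicle"
    t_exit: np.datetime64  # crossing of the 100 m home reference radius
    t_enter: np.datetime64


@dataclass
class ParticipantTruth:
    participant_id: str
    home_lat: float
    home_lon: float
    trips: list[TrueTrip]
    sleep_windows: list  # [(start, end)] whole-minute grid
    minute_classes: np.ndarray  # int8, length days*1440
    in_home_social_per_day: np.ndarray
    covariates: dict
    start: np.datetime64
    days: int

    def trips_on_day(self, day: int) -> list[TrueTrip]:
        d0 = self.start + np.timedelta64(day * 86400, "s")
        d1 = d0 + np.timedelta64(86400, "s")
        return [t for t in self.trips if d0 <= t.departure < d1]


@dataclass
class GroundTruth:
    participants: dict  # participant_id -> ParticipantTruth

    def total_trips(self, participant_id: str) -> int:
        return len(self.participants[participant_id].trips)


# --------------------------------------------------------------------------
# Gazetteer and home sites
# --------------------------------------------------------------------------


def build_gazetteer() -> Gazetteer:
    """The synthetic town's geofence gazetteer (deterministic)."""
    frame = LocalFrame(*TOWN_CENTER)
    feats = []
    for name, cat, x, y, r in _FENCES_XY:
        lat, lon = frame.to_latlon(x, y)
        feats.append(GeoFence(name, float(lat), float(lon), r, cat))
    return Gazetteer(feats)


def _home_sites(n: int) -> np.ndarray:
    """First n home sites on a 300 m grid west of the destination fences.

    Sites closer than 450 m to any geofence centre are skipped so the home
    anchor never overlaps a destination fence.
    """
    fences = np.array([(x, y) for _, _, x, y, _ in _FENCES_XY])
    sites = []
    col = 0
    while len(sites) < n:
        x = -1200.0 - 300.0 * (col + 1)
        for row in range(14):
            y = -1950.0 + 300.0 * row
            if np.min(np.hypot(fences[:, 0] - x, fences[:, 1] - y)) >= 450.0:
                sites.append((x, y))
                if len(sites) == n:
                    break
        col += 1
        if col > 500:  # pragma: no cover - defensive
            raise RuntimeError("could not place home sites")
    return np.array(sites)


# --------------------------------------------------------------------------
# Per-participant simulation
# --------------------------------------------------------------------------


def _draw_weekly_trips(profile: SimProfile, rng: np.random.Generator) -> int:
    q1, q3 = profile.trips_per_week_iqr
    sigma = max((q3 - q1) / 1.349, 0.5)
    n = rng.normal(profile.trips_per_week_median, sigma)
    return int(np.clip(round(n), 0, 35))


def _allocate_to_days(total: int, days: int, rng: np.random.Generator,
                      cap: int = 5) -> np.ndarray:
    """Spread a participant's trips across monitoring days (uniform multinomial).

    The within-week distribution of trips across days is a modelling free
    choice; a capped uniform multinomial keeps schedules feasible.
    """
    counts = rng.multinomial(total, np.full(days, 1.0 / days))
    # redistribute overflow above the per-day capacity
    for _ in range(4 * days):
        over = np.flatnonzero(counts > cap)
        if over.size == 0:
            break
        under = np.flatnonzero(counts < cap)
        if under.size == 0:
            counts = np.minimum(counts, cap)
            break
        counts[over[0]] -= 1
        counts[rng.choice(under)] += 1
    return counts


def _nearest_fence(gaz: Gazetteer, category: str, lat: float, lon: float) -> GeoFence:
    cands = gaz.of_category(category)
    if not cands:
        raise ValueError(f"no geofence of category {category!r} in gazetteer")
    d = [haversine_m(lat, lon, f.lat, f.lon) for f in cands]
    return cands[int(np.argmin(d))]


def _simulate_participant(
    pid: str,
    home_xy: np.ndarray,
    profile: SimProfile,
    gaz: Gazetteer,
    frame: LocalFrame,
    rng: np.random.Generator,
) -> ParticipantTruth:
    start = as_dt64(profile.monitoring_start)
    days = profile.days
    home_lat, home_lon = (float(v) for v in frame.to_latlon(*home_xy))
    weights = profile.weight_vector()

    weekly = _draw_weekly_trips(profile, rng)
    total_trips = int(round(weekly * days / 7.0))
    per_day = _allocate_to_days(total_trips, days, rng)

    # --- sleep: one nocturnal window at the start of each monitoring day ---
    sleep_windows = []
    sleep_min = np.zeros(days, dtype=int)
    for d in range(days):
        off = int(rng.uniform(0, 30))
        dur = int(np.clip(rng.normal(profile.sleep_min_per_night, profile.sleep_sd_min),
                          360, 600))
        w0 = start + np.timedelta64(d * 1440 + off, "m").astype("timedelta64[s]")
        w1 = w0 + np.timedelta64(dur, "m").astype("timedelta64[s]")
        sleep_windows.append((w0, w1))
        sleep_min[d] = dur

    # --- trip schedules on a whole-minute grid ---
    trips: list[TrueTrip] = []
    for d in range(days):
        day0_min = d * 1440
        wake = int((sleep_windows[d][1] - start) / np.timedelta64(60, "s")) - day0_min
        cursor = wake + int(rng.uniform(30, 90))
        for _ in range(int(per_day[d])):
            cat = str(rng.choice(CATEGORIES, p=weights))
            trip = _build_trip(
                cat, home_xy, home_lat, home_lon, gaz, frame, rng, weights,
                profile.two_stop_prob,
            )
            if trip is None:
                continue
            legs_min, visits_spec, mode, exit_frac, enter_frac = trip
            dur = sum(legs_min) + sum(v[1] for v in visits_spec)
            if cursor + dur > 1305:  # must be home by 21:45 local
                break
            dep_min = day0_min + cursor
            trips.append(
                _materialise_trip(
                    start, dep_min, legs_min, visits_spec, mode,
                    exit_frac, enter_frac, rng,
                )
            )
            cursor += dur + int(rng.uniform(15, 120))
    trips.sort(key=lambda t: t.departure)

    # --- per-minute intensity classes -------------------------------------
    minutes = days * 1440
    classes = np.full(minutes, SEDENTARY, dtype=np.int8)
    for w0, w1 in sleep_windows:
        m0 = int((w0 - start) / np.timedelta64(60, "s"))
        m1 = int((w1 - start) / np.timedelta64(60, "s"))
        classes[m0:m1] = SLEEP

    in_trip = np.zeros(minutes, dtype=bool)
    protected = np.zeros(minutes, dtype=bool)  # no at-home MVPA near trip edges
    for t in trips:
        m0 = int((t.departure - start) / np.timedelta64(60, "s"))
        m1 = int((t.return_ - start) / np.timedelta64(60, "s"))
        in_trip[m0:m1] = True
        protected[max(0, m0 - 2): min(minutes, m1 + 2)] = True
        if t.mode == "walk":
            classes[m0:m1] = MODERATE
            classes[m0: m0 + 2] = LIGHT  # edge minutes stay sub-MVPA so that
            classes[max(m0, m1 - 2): m1] = LIGHT  # home/away tallies are exact
        else:
            classes[m0:m1] = SEDENTARY  # vehicle travel
            for v in t.visits:
                vm0 = int((v.arrival - start) / np.timedelta64(60, "s"))
                vm1 = int((v.departure - start) / np.timedelta64(60, "s"))
                classes[vm0:vm1] = LIGHT

    # --- at-home MVPA topping up the daily target --------------------------
    expected_walk = (
        profile.trips_per_week_median
        * profile.category_visit_weights.get("local_walk_greenspace", 0.0)
        * _MEAN_WALK_TRIP_MVPA_MIN
        / 7.0
    )
    base = max(5.0, rng.normal(profile.mvpa_min_per_day - expected_walk,
                               _MVPA_PARTICIPANT_SD))
    vigorous_capable = rng.random() < 0.39
    for d in range(days):
        s = slice(d * 1440, (d + 1) * 1440)
        day_cls = classes[s]
        # at-home MVPA is additive to walk-trip MVPA, so the participant's
        # daily mean is base + (walk minutes), keeping the baseline analytic
        target = max(0.0, rng.normal(base, _MVPA_DAY_SD))
        extra = int(round(target))
        eligible = np.flatnonzero(
            (day_cls == SEDENTARY) & ~in_trip[s] & ~protected[s]
        )
        if extra and eligible.size:
            take = rng.choice(eligible, size=min(extra, eligible.size), replace=False)
            vig = 0
            if vigorous_capable:
                vig = min(int(rng.integers(0, 3)), take.size)
            day_cls[take[:vig]] = VIGOROUS
            day_cls[take[vig:]] = MODERATE

    # --- convert surplus sedentary time to light to hit the sedentary target
    sed_centre = rng.normal(profile.sedentary_min_per_day, profile.sedentary_sd_min)
    for d in range(days):
        s = slice(d * 1440, (d + 1) * 1440)
        day_cls = classes[s]
        waking = 1440 - int(np.sum(day_cls == SLEEP))
        mvpa = int(np.sum((day_cls == MODERATE) | (day_cls == VIGOROUS)))
        light_now = int(np.sum(day_cls == LIGHT))
        sed_target = float(np.clip(rng.normal(sed_centre, 25.0), 0, waking))
        need_light = int(round(waking - mvpa - sed_target)) - light_now
        if need_light > 0:
            pool = np.flatnonzero((day_cls == SEDENTARY) & ~in_trip[s])
            if pool.size:
                take = rng.choice(pool, size=min(need_light, pool.size), replace=False)
                day_cls[take] = LIGHT

    # --- social interactions ----------------------------------------------
    for t in trips:
        for v in t.visits:
            v.social_interactions = int(rng.poisson(_SOCIAL_MEAN.get(v.category, 0.0)))
    in_home_social = rng.poisson(0.35, size=days)

    covariates = {
        "age": float(np.round(np.clip(rng.normal(74, 5), 65, 95), 1)),
        "hrqol": float(np.round(np.clip(rng.normal(0.84, 0.08), 0.2, 1.0), 3)),
        "loneliness": int(np.clip(round(rng.normal(1.4, 1.4)), 0, 6)),
        "sleep_quality": int(np.clip(round(rng.normal(5.41, 3.0)), 0, 21)),
    }

    return ParticipantTruth(
        participant_id=pid,
        home_lat=home_lat,
        home_lon=home_lon,
        trips=trips,
        sleep_windows=sleep_windows,
        minute_classes=classes,
        in_home_social_per_day=in_home_social,
        covariates=covariates,
        start=start,
        days=days,
    )


def _build_trip(category, home_xy, home_lat, home_lon, gaz, frame, rng, weights,
                two_stop_prob=0.0):
    """Plan one trip: travel legs (minutes) and visit dwell times.

    Returns (legs_min, visits_spec, mode, exit_frac, enter_frac) where
    visits_spec is [(fence, dwell_min, stop_xy)] and the fracs locate the
    crossing of the 100 m home reference radius within the first/last leg.
    """
    if category == "local_walk_greenspace":
        mode, speed = "walk", WALK_SPEED_MS
        fence = _nearest_fence(gaz, category, home_lat, home_lon)
        fences = [fence]
    else:
        mode, speed = "vehicle", VEHICLE_SPEED_MS
        cands = gaz.of_category(category)
        if not cands:
            raise ValueError(f"no geofence of category {category!r} in gazetteer")
        fences = [cands[int(rng.integers(len(cands)))]]
        if rng.random() < two_stop_prob:  # occasional two-stop outing
            others = [c for c in CATEGORIES if c != "local_walk_greenspace"]
            w = np.array([weights[CATEGORIES.index(c)] for c in others])
            if w.sum() > 0:
                cat2 = str(rng.choice(others, p=w / w.sum()))
                # a second stop must be a distinct venue, else keep one stop
                cands2 = [f for f in gaz.of_category(cat2)
                          if f.name != fences[0].name]
                if cands2:
                    fences.append(cands2[int(rng.integers(len(cands2)))])

    stops = []
    for f in fences:
        fx, fy = frame.to_xy(f.lat, f.lon)
        ang = rng.uniform(0, 2 * np.pi)
        rad = f.radius_m * 0.4 * np.sqrt(rng.uniform())
        stops.append((f, np.array([float(fx) + rad * np.cos(ang),
                                   float(fy) + rad * np.sin(ang)])))

    pts = [np.asarray(home_xy, dtype=float)] + [s[1] for s in stops] + [
        np.asarray(home_xy, dtype=float)
    ]
    legs_min, dists = [], []
    for a, b in zip(pts[:-1], pts[1:]):
        dist = float(np.hypot(*(b - a)))
        dists.append(dist)
        legs_min.append(max(1, int(math.ceil(dist / (speed * 60.0)))))
    visits_spec = []
    for f, xy in stops:
        lo, hi = _DWELL_RANGE[f.category]
        visits_spec.append((f, int(rng.integers(lo, hi + 1)), xy))

    exit_frac = min(1.0, HOME_REFERENCE_RADIUS_M / max(dists[0], 1.0))
    enter_frac = min(1.0, HOME_REFERENCE_RADIUS_M / max(dists[-1], 1.0))
    return legs_min, visits_spec, mode, exit_frac, enter_frac


def _materialise_trip(start, dep_min, legs_min, visits_spec, mode,
                      exit_frac, enter_frac, rng) -> TrueTrip:
    dep = start + np.timedelta64(dep_min, "m").astype("timedelta64[s]")
    t = dep
    visits = []
    for leg, (f, dwell, xy) in zip(legs_min[:-1], visits_spec):
        arr = t + np.timedelta64(leg, "m").astype("timedelta64[s]")
        leave = arr + np.timedelta64(dwell, "m").astype("timedelta64[s]")
        frame = LocalFrame(*TOWN_CENTER)
        lat, lon = frame.to_latlon(xy[0], xy[1])
        visits.append(TrueVisit(f.category, f.name, arr, leave, float(lat), float(lon)))
        t = leave
    ret = t + np.timedelta64(legs_min[-1], "m").astype("timedelta64[s]")
    t_exit = dep + np.timedelta64(int(round(legs_min[0] * 60 * exit_frac)), "s")
    t_enter = ret - np.timedelta64(int(round(legs_min[-1] * 60 * enter_frac)), "s")
    return TrueTrip(dep, ret, visits, mode, t_exit, t_enter)


# --------------------------------------------------------------------------
# GPS emission
# --------------------------------------------------------------------------


def emit_gps_track(
    schedule: list[TrueTrip],
    home: tuple[float, float],
    gazetteer: Gazetteer,
    epoch_s: int,
    seed: int,
    start=None,
    days: int = 7,
    participant_id: str = "P000",
) -> GpsTrack:
    """Emit a loss-free GPS track realising a trip schedule.

    Fixes sit at the home coordinates (small jitter) when at home, travel on
    straight constant-speed lines to each visit's stop point, and jitter
    around the stop point during the dwell.
    """
    for trip in schedule:
        for v in trip.visits:
            if not gazetteer.of_category(v.category):
                raise ValueError(
                    f"visit category {v.category!r} absent from gazetteer"
                )
    rng = np.random.default_rng(seed)
    start = as_dt64(start if start is not None else _DEFAULT_START)
    frame = LocalFrame(*TOWN_CENTER)
    hx, hy = (float(v) for v in frame.to_xy(*home))

    n = days * 86400 // epoch_s
    rel_s = np.arange(n, dtype=np.int64) * epoch_s
    x = np.full(n, hx) + rng.normal(0, HOME_JITTER_SD_M, n)
    y = np.full(n, hy) + rng.normal(0, HOME_JITTER_SD_M, n)

    def idx(t: np.datetime64) -> int:
        s = int((t - start) / np.timedelta64(1, "s"))
        return int(math.ceil(s / epoch_s))

    for trip in schedule:
        # waypoints: (time, xy) at home departure, each arrival/leave, return
        way = [(trip.departure, (hx, hy))]
        for v in trip.visits:
            vx, vy = (float(c) for c in frame.to_xy(v.lat, v.lon))
            way.append((v.arrival, (vx, vy)))
            way.append((v.departure, (vx, vy)))
        way.append((trip.return_, (hx, hy)))
        for (t0, p0), (t1, p1) in zip(way[:-1], way[1:]):
            i0, i1 = idx(t0), idx(t1)
            if i1 <= i0:
                continue
            i0c, i1c = max(0, i0), min(n, i1)
            seg = slice(i0c, i1c)
            span = float((t1 - t0) / np.timedelta64(1, "s"))
            frac = (rel_s[seg] - int((t0 - start) / np.timedelta64(1, "s"))) / span
            jx = rng.normal(0, STOP_JITTER_SD_M, i1c - i0c)
            jy = rng.normal(0, STOP_JITTER_SD_M, i1c - i0c)
            x[seg] = p0[0] + frac * (p1[0] - p0[0]) + jx
            y[seg] = p0[1] + frac * (p1[1] - p0[1]) + jy

    lat, lon = frame.to_latlon(x, y)
    track = GpsTrack(
        participant_id=participant_id,
        timestamps=start + rel_s.astype("timedelta64[s]"),
        lat=lat,
        lon=lon,
        nominal_epoch_s=epoch_s,
    )
    track.validate()
    return track


def inject_signal_loss(track: GpsTrack, loss_hours: float, seed: int,
                       max_block_h: float = 6.0) -> GpsTrack:
    """Delete contiguous epoch-aligned blocks totalling ``loss_hours``.

    Emulates GPS dropout (device off, urban canyons, overnight charging).
    Blocks never exceed ``max_block_h`` so that no monitoring day loses
    enough recording to trip the daily validity gate on its own.  The first
    fix after each block is recorded as a resume point, where the CSV writer
    inserts a spurious device-header ("title") line for the cleaner to drop.
    """
    if loss_hours < 0:
        raise ValueError("loss_hours must be >= 0")
    span_h = float(
        (track.timestamps[-1] - track.timestamps[0]) / np.timedelta64(3600, "s")
    )
    if loss_hours > span_h + 1e-9:
        raise ValueError("loss_hours exceeds track span")
    if loss_hours == 0:
        return track

    rng = np.random.default_rng(seed)
    eps = track.nominal_epoch_s
    n_loss = int(round(loss_hours * 3600.0 / eps))
    if n_loss == 0:
        return track
    k = max(int(math.ceil(loss_hours / 2.5)), int(math.ceil(loss_hours / max_block_h)))
    k = min(k, n_loss)
    lens = rng.multinomial(n_loss - k, np.full(k, 1.0 / k)) + 1
    # cap block lengths, pushing overflow round-robin onto other blocks
    cap = int(max_block_h * 3600 / eps)
    for _ in range(10 * k):
        over = np.flatnonzero(lens > cap)
        under = np.flatnonzero(lens < cap)
        if over.size == 0 or under.size == 0:
            break
        move = min(int(lens[over[0]] - cap), int(cap - lens[under[0]]))
        lens[over[0]] -= move
        lens[under[0]] += move

    start = track.timestamps[0]
    grid = ((track.timestamps - start) / np.timedelta64(eps, "s")).astype(np.int64)
    n_grid = int(grid[-1]) + 1
    free = n_grid - n_loss
    if free <= 0:
        raise ValueError("loss_hours leaves no data")
    offsets = np.sort(rng.integers(0, free + 1, size=k))
    starts = offsets + np.concatenate(([0], np.cumsum(lens[:-1])))

    remove = np.zeros(n_grid + 1, dtype=bool)
    for s0, ln in zip(starts, lens):
        remove[s0: s0 + ln] = True
    keep = ~remove[grid]

    kept_ts = track.timestamps[keep]
    resumes = []
    for s0, ln in zip(starts, lens):
        after = kept_ts[kept_ts > start + np.timedelta64(int((s0 + ln - 1) * eps), "s")]
        if after.size:
            resumes.append(after[0])
    return GpsTrack(
        participant_id=track.participant_id,
        timestamps=kept_ts,
        lat=track.lat[keep],
        lon=track.lon[keep],
        nominal_epoch_s=eps,
        resume_points=np.array(sorted(set(resumes)), dtype="datetime64[s]"),
    )


# --------------------------------------------------------------------------
# Accelerometer emission
# --------------------------------------------------------------------------

#: Count bands per 60-s epoch implied by the cut points (light 283, moderate
#: 605, vigorous 1697).  Sleep draws sit well below the light band.
_BANDS_60S = {
    SLEEP: (0.5, 60.0),
    SEDENTARY: (0.5, 283.0),
    LIGHT: (283.0, 605.0),
    MODERATE: (605.0, 1697.0),
    VIGOROUS: (1697.0, 4000.0),
}
_LOGNORM_SIGMA = 0.5


def _truncated_lognormal(lo, hi, size, rng):
    """Lognormal(mu, sigma) truncated to [lo, hi), mu at the band's geometric
    midpoint so draws cluster mid-band."""
    mu = 0.5 * (np.log(lo) + np.log(hi))
    a = ndtr((np.log(lo) - mu) / _LOGNORM_SIGMA)
    b = ndtr((np.log(hi) - mu) / _LOGNORM_SIGMA)
    u = rng.uniform(a, b, size)
    return np.exp(mu + _LOGNORM_SIGMA * ndtri(u))


def emit_accel_series(truth: ParticipantTruth, epoch_s: int, seed: int) -> EpochSeries:
    """Counts per epoch drawn from class-conditioned truncated lognormals.

    Calibrated so that cut-point classification at any epoch length that
    divides 60 s reproduces the ground-truth minute classes exactly: each
    sub-minute draw lies in the minute's band scaled by ``epoch_s/60``, so
    both per-epoch classification and 60-s aggregate classification recover
    the truth.
    """
    if 60 % epoch_s != 0:
        raise ValueError("accelerometer epoch must divide 60 s")
    rng = np.random.default_rng(seed)
    per_min = 60 // epoch_s
    cls_epochs = np.repeat(truth.minute_classes, per_min)
    counts = np.empty(cls_epochs.size, dtype=float)
    scale = epoch_s / 60.0
    for cls, (lo, hi) in _BANDS_60S.items():
        m = cls_epochs == cls
        if not m.any():
            continue
        # shrink the top of the band so sums of sub-minute draws stay inside
        counts[m] = _truncated_lognormal(lo * scale, hi * scale * 0.999, int(m.sum()), rng)
    series = EpochSeries(
        participant_id=truth.participant_id,
        start=truth.start,
        epoch_s=epoch_s,
        counts=np.round(counts, 4),
    )
    series.validate()
    return series


# --------------------------------------------------------------------------
# Diary emission
# --------------------------------------------------------------------------


def emit_diary(
    truth: ParticipantTruth,
    overreport_rate: float,
    jitter_min: float,
    seed: int,
) -> list[DiaryEntry]:
    """Self-report diary: one entry per true trip (times jittered), plus
    Poisson-distributed phantom short trips emulating over-reporting, plus
    in-home activities with social interactions and nightly sleep entries.
    """
    if jitter_min < 0:
        raise ValueError("jitter_min must be >= 0")
    rng = np.random.default_rng(seed)
    entries: list[DiaryEntry] = []

    def jit() -> np.timedelta64:
        return np.timedelta64(int(round(rng.uniform(-jitter_min, jitter_min))), "m")

    for t in truth.trips:
        s = t.departure + jit()
        e = t.return_ + jit()
        if e <= s:
            e = s + np.timedelta64(5, "m")
        cat = t.visits[0].category if t.visits else "local_walk_greenspace"
        entries.append(
            DiaryEntry(
                start=s,
                end=e,
                activity=_ACTIVITY_TEXT.get(cat, "outing"),
                reported_category=cat,
                social_interactions=int(sum(v.social_interactions for v in t.visits)),
            )
        )

    # phantom (over-reported) short trips
    n_phantom = rng.poisson(overreport_rate * truth.days / 7.0)
    cats = list(_PHANTOM_WEIGHTS)
    p = np.array([_PHANTOM_WEIGHTS[c] for c in cats])
    for _ in range(int(n_phantom)):
        d = int(rng.integers(truth.days))
        start_min = d * 1440 + int(rng.uniform(9 * 60, 20 * 60))
        dur = int(rng.integers(10, 26))
        s = truth.start + np.timedelta64(start_min, "m").astype("timedelta64[s]")
        cat = str(rng.choice(cats, p=p))
        entries.append(
            DiaryEntry(
                start=s,
                end=s + np.timedelta64(dur, "m").astype("timedelta64[s]"),
                activity="quick " + _ACTIVITY_TEXT.get(cat, "outing"),
                reported_category=cat,
                social_interactions=0,
            )
        )

    # in-home activities (gardening counts as in-home) and sleep entries
    for d in range(truth.days):
        base = truth.start + np.timedelta64(d * 1440, "m").astype("timedelta64[s]")
        morning = base + np.timedelta64(9 * 60 + int(rng.uniform(0, 60)), "m")
        evening = base + np.timedelta64(19 * 60 + int(rng.uniform(0, 60)), "m")
        entries.append(
            DiaryEntry(
                start=morning,
                end=morning + np.timedelta64(45, "m"),
                activity=str(rng.choice(_HOME_ACTIVITIES)),
                reported_category="home",
                social_interactions=int(truth.in_home_social_per_day[d]),
            )
        )
        entries.append(
            DiaryEntry(
                start=evening,
                end=evening + np.timedelta64(90, "m"),
                activity="watching television",
                reported_category="home",
            )
        )
    for w0, w1 in truth.sleep_windows:
        entries.append(
            DiaryEntry(
                start=w0, end=w1, activity="sleep",
                reported_category="home", is_sleep=True,
            )
        )
    entries.sort(key=lambda e: e.start)
    for e in entries:
        e.validate()
    return entries


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


def generate_cohort(
    profile: SimProfile,
) -> tuple[list[ParticipantBundle], GroundTruth, Gazetteer]:
    """Generate a ground-truthed cohort (deterministic given profile.seed)."""
    gaz = build_gazetteer()
    frame = LocalFrame(*TOWN_CENTER)
    homes = _home_sites(profile.n_participants)
    master = np.random.default_rng(profile.seed)

    bundles: list[ParticipantBundle] = []
    truths: dict[str, ParticipantTruth] = {}
    for i in range(profile.n_participants):
        pid = f"P{i + 1:03d}"
        prng = np.random.default_rng([profile.seed, i])
        truth = _simulate_participant(pid, homes[i], profile, gaz, frame, prng)
        truths[pid] = truth

        gps_seed = int(prng.integers(2**31))
        track = emit_gps_track(
            truth.trips,
            (truth.home_lat, truth.home_lon),
            gaz,
            profile.gps_epoch_s,
            gps_seed,
            start=profile.monitoring_start,
            days=profile.days,
            participant_id=pid,
        )
        span_h = profile.days * 24.0
        loss = float(
            min(prng.exponential(profile.gps_loss_hours_mean), 0.6 * span_h)
            if profile.gps_loss_hours_mean > 0
            else 0.0
        )
        track = inject_signal_loss(track, loss, seed=int(prng.integers(2**31)))

        accel = (
            None
            if i in profile.accel_malfunction_ids
            else emit_accel_series(truth, profile.accel_epoch_s,
                                   seed=int(prng.integers(2**31)))
        )
        diary = (
            None
            if i in profile.missing_diary_ids
            else emit_diary(
                truth,
                profile.diary_overreport_rate,
                profile.diary_jitter_min,
                seed=int(prng.integers(2**31)),
            )
        )
        bundles.append(
            ParticipantBundle(
                participant_id=pid,
                gps=track,
                accel=accel,
                diary=diary,
                covariates=dict(truth.covariates),
            )
        )
    del master  # reserved for future cohort-level draws
    return bundles, GroundTruth(truths), gaz


# --------------------------------------------------------------------------
# Plain-text writers (CSV / GeoJSON-like)
# --------------------------------------------------------------------------

#: Qstarz-style header text re-emitted by the logger after signal interruption.
TITLE_LINE = (
    "INDEX,RCR,UTC DATE,UTC TIME,LOCAL DATE,LOCAL TIME,MS,VALID,"
    "LATITUDE,N/S,LONGITUDE,E/W"
)


def write_cohort(bundles, gazetteer: Gazetteer, out_dir) -> None:
    """Write a cohort as the pipeline's plain-text external formats.

    gps.csv gains a spurious device-header line at every dropout resume
    point, exercising the ingest cleaner.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "gps.csv", "w") as fh:
        fh.write("participant_id,timestamp,lat,lon\n")
        for b in bundles:
            if b.gps is None:
                continue
            resumes = set(np.asarray(b.gps.resume_points).tolist())
            ts = b.gps.timestamps.tolist()
            for t, la, lo in zip(ts, b.gps.lat, b.gps.lon):
                if t in resumes:
                    fh.write(TITLE_LINE + "\n")
                fh.write(
                    f"{b.participant_id},{t.isoformat()},{float(la)!r},{float(lo)!r}\n"
                )

    with open(out / "accel.csv", "w") as fh:
        fh.write("participant_id,timestamp,epoch_s,count\n")
        for b in bundles:
            if b.accel is None:
                continue
            for t, c in zip(b.accel.timestamps.tolist(), b.accel.counts):
                fh.write(
                    f"{b.participant_id},{t.isoformat()},"
                    f"{b.accel.epoch_s},{float(c)!r}\n"
                )

    with open(out / "diary.csv", "w") as fh:
        fh.write(
            "participant_id,start,end,activity,category,"
            "social_interactions,is_sleep,is_nonwear\n"
        )
        for b in bundles:
            if b.diary is None:
                continue
            for e in b.diary:
                fh.write(
                    f"{b.participant_id},{e.start.item().isoformat()},"
                    f"{e.end.item().isoformat()},{e.activity},"
                    f"{e.reported_category},{e.social_interactions},"
                    f"{int(e.is_sleep)},{int(e.is_nonwear)}\n"
                )

    rows = [
        {"participant_id": b.participant_id, **b.covariates} for b in bundles
    ]
    pd.DataFrame(rows).to_csv(out / "covariates.csv", index=False)

    write_gazetteer(gazetteer, out / "gazetteer.json")


def write_gazetteer(gazetteer: Gazetteer, path) -> None:
    doc = {
        "features": [
            {
                "name": f.name,
                "category": f.category,
                "center": {"lat": f.lat, "lon": f.lon},
                "radius_m": f.radius_m,
            }
            for f in gazetteer.features
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1))
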