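"""Home-anchor estimation, out-of-home trip ("loop") detection, dwell-based
visit extraction, and gazetteer categorisation.

A trip opens when two consecutive fixes fall outside the home geofence and
closes when two consecutive fixes return inside; signal gaps up to a bridge
tolerance are carried through, and a long gap that starts away from home but
resumes at home closes the loop at the last out-of-home fix.  None of these
thresholds is canonical — all defaults (home radius 100 m, minimum trip 5
min, bridge 10 min, dwell radius 50 m, minimum dwell 5 min, snap 100 m) are
declared stand-ins, configurable and echoed into every run report.
"""
from __future__ import annotations

import logging

import numpy as np

from .geo import LocalFrame, haversine_m
from .types import (
    CATEGORIES,
    DataLossReport,
    Gazetteer,
    GpsTrack,
    HomeAnchor,
    LocationVisit,
    TripEpisode,
)

log = logging.getLogger(__name__)

DEFAULTS = dict(
    home_radius_m=100.0,
    min_trip_min=5.0,
    bridge_gap_min=10.0,
    dwell_radius_m=50.0,
    min_dwell_min=5.0,
    max_snap_m=100.0,
    neighbourhood_radius_m=1000.0,
)


# --------------------------------------------------------------------------
# Home anchor
# --------------------------------------------------------------------------


def estimate_home(
    track: GpsTrack,
    nocturnal_window: tuple[int, int] = (0, 6),
    cell_m: float = 50.0,
    radius_m: float = 100.0,
) -> HomeAnchor:
    """Locate the home as the densest nocturnal spatial cluster.

    Nocturnal fixes (local hour in ``nocturnal_window``, wrap allowed) are
    binned on a ~50 m grid; the modal cell's member fixes are averaged.
    Ties break to the southwest-most cell (deterministic, logged).
    """
    if track.n_fixes == 0:
        raise ValueError("cannot estimate home from an empty track; "
                         "provide explicit home coordinates")
    h0, h1 = nocturnal_window
    tod_h = (track.timestamps.astype("datetime64[s]").astype(np.int64) % 86400) / 3600.0
    mask = (tod_h >= h0) & (tod_h < h1) if h0 <= h1 else (tod_h >= h0) | (tod_h < h1)
    if not mask.any():
        raise ValueError(
            "no nocturnal fixes; provide explicit home coordinates in config"
        )
    lat, lon = track.lat[mask], track.lon[mask]
    frame = LocalFrame(float(np.mean(lat)), float(np.mean(lon)))
    x, y = frame.to_xy(lat, lon)
    cx = np.floor(x / cell_m).astype(np.int64)
    cy = np.floor(y / cell_m).astype(np.int64)
    cells, inverse, counts = np.unique(
        np.stack([cy, cx], axis=1), axis=0, return_inverse=True, return_counts=True
    )
    best = counts == counts.max()
    if best.sum() > 1:
        log.warning(
            "%s: %d equally dense nocturnal cells; using southwest-most",
            track.participant_id, int(best.sum()),
        )
    # southwest-most: smallest y (south), then smallest x (west); np.unique
    # already sorts rows lexicographically by (cy, cx)
    winner = int(np.flatnonzero(best)[0])
    members = inverse == winner
    mlat, mlon = frame.to_latlon(float(np.mean(x[members])), float(np.mean(y[members])))
    return HomeAnchor(lat=float(mlat), lon=float(mlon), radius_m=radius_m)


# --------------------------------------------------------------------------
# Trip detection
# --------------------------------------------------------------------------


def _runs(values: np.ndarray):
    """Run-length encode a boolean array as (value, i0, i1_inclusive)."""
    if values.size == 0:
        return []
    change = np.flatnonzero(np.diff(values.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [values.size - 1]))
    return [(bool(values[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def detect_trips(
    track: GpsTrack,
    home: HomeAnchor,
    min_trip_min: float = 5.0,
    bridge_gap_min: float = 10.0,
) -> list[TripEpisode]:
    """Detect out-of-home loops from the home-membership sequence.

    Open on >= 2 consecutive fixes outside the home radius; close on >= 2
    consecutive fixes back inside (return time = first inside fix).  Signal
    gaps <= ``bridge_gap_min`` within an episode are bridged; a longer gap
    that resumes inside the home radius closes the loop at the last
    out-of-home fix.  Episodes shorter than ``min_trip_min`` are discarded.
    """
    if track.n_fixes == 0:
        return []
    ts = track.timestamps
    inside = haversine_m(track.lat, track.lon, home.lat, home.lon) <= home.radius_m
    bridge = np.timedelta64(int(round(bridge_gap_min * 60)), "s")

    trips: list[TripEpisode] = []
    state_out = False
    open_i0 = -1
    for val, i0, i1 in _runs(inside):
        if not state_out:
            if not val and (i1 - i0 + 1) >= 2:
                state_out = True
                open_i0 = i0
        else:
            if val:
                gap_big = i0 > 0 and (ts[i0] - ts[i0 - 1]) > bridge
                if gap_big:
                    trips.append(
                        TripEpisode(
                            departure=ts[open_i0], return_=ts[i0 - 1],
                            complete_loop=True, i0=open_i0, i1=i0 - 1,
                        )
                    )
                    state_out = False
                elif (i1 - i0 + 1) >= 2:
                    trips.append(
                        TripEpisode(
                            departure=ts[open_i0], return_=ts[i0],
                            complete_loop=True, i0=open_i0, i1=i0 - 1,
                        )
                    )
                    state_out = False
            # single inside fix (blip) without a long gap: stay in the trip
    if state_out:
        trips.append(
            TripEpisode(
                departure=ts[open_i0], return_=ts[-1],
                complete_loop=False, i0=open_i0, i1=track.n_fixes - 1,
            )
        )
    return [t for t in trips if t.duration_min >= min_trip_min]


# --------------------------------------------------------------------------
# Visit extraction and categorisation
# --------------------------------------------------------------------------


def detect_visits(
    trip: TripEpisode,
    track: GpsTrack,
    dwell_radius_m: float = 50.0,
    min_dwell_min: float = 5.0,
) -> list[LocationVisit]:
    """Extract dwell-based stops within a trip.

    A visit is a maximal run of fixes staying within ``dwell_radius_m`` of
    its running centroid and lasting >= ``min_dwell_min``.  Travel segments
    between visits carry no category.
    """
    i0, i1 = trip.i0, trip.i1
    if i0 < 0 or i1 < i0:
        return []
    lat = track.lat[i0: i1 + 1]
    lon = track.lon[i0: i1 + 1]
    ts = track.timestamps[i0: i1 + 1]
    frame = LocalFrame(float(lat[0]), float(lon[0]))
    x, y = frame.to_xy(lat, lon)

    visits: list[LocationVisit] = []

    def flush(a: int, b: int, cx: float, cy: float) -> None:
        dwell = (ts[b] - ts[a]) / np.timedelta64(60, "s")
        if dwell >= min_dwell_min:
            vlat, vlon = frame.to_latlon(cx, cy)
            visits.append(
                LocationVisit(
                    arrival=ts[a], departure=ts[b],
                    lat=float(vlat), lon=float(vlon),
                )
            )

    a = 0
    sx, sy, cnt = float(x[0]), float(y[0]), 1
    for k in range(1, x.size):
        cx, cy = sx / cnt, sy / cnt
        if np.hypot(x[k] - cx, y[k] - cy) <= dwell_radius_m:
            sx += float(x[k])
            sy += float(y[k])
            cnt += 1
        else:
            flush(a, k - 1, cx, cy)
            a, sx, sy, cnt = k, float(x[k]), float(y[k]), 1
    flush(a, x.size - 1, sx / cnt, sy / cnt)
    return visits


def categorize_visit(
    visit: LocationVisit, gazetteer: Gazetteer, max_snap_m: float = 100.0
) -> LocationVisit:
    """Assign the category of the geofence containing the visit centroid.

    If several fences contain it, the nearest centre wins; an exact tie
    breaks by the category listing order.  A centroid inside no fence snaps
    to the nearest fence edge within ``max_snap_m``, else stays unknown.
    """
    best_cat, best_key = "unknown", None
    for f in gazetteer.features:
        d = float(haversine_m(visit.lat, visit.lon, f.lat, f.lon))
        if d <= f.radius_m:
            key = (0.0, d, CATEGORIES.index(f.category))
        elif d - f.radius_m <= max_snap_m:
            key = (1.0, d - f.radius_m, CATEGORIES.index(f.category))
        else:
            continue
        if best_key is None or key < best_key:
            best_key, best_cat = key, f.category
    visit.category = best_cat
    return visit


def classify_walk_loop(
    trip: TripEpisode,
    track: GpsTrack,
    home: HomeAnchor,
    neighbourhood_radius_m: float = 1000.0,
) -> bool:
    """A visit-less loop staying within the neighbourhood of home is a local
    walk/greenspace outing (the walk itself is the visited location)."""
    if trip.visits or trip.i0 < 0:
        return False
    d = haversine_m(
        track.lat[trip.i0: trip.i1 + 1], track.lon[trip.i0: trip.i1 + 1],
        home.lat, home.lon,
    )
    return bool(np.max(d) <= neighbourhood_radius_m)


def count_participation(trips: list[TripEpisode]) -> dict:
    """Total trips and visit counts per category over the window.

    A trip may contribute zero or several visits, so category counts need
    not sum to the trip count.  Visit-less neighbourhood walk loops count
    one local walk/greenspace visit each.
    """
    by_cat = {c: 0 for c in CATEGORIES}
    unknown = 0
    for t in trips:
        if t.walk_loop:
            by_cat["local_walk_greenspace"] += 1
            continue
        for v in t.visits:
            if v.category in by_cat:
                by_cat[v.category] += 1
            else:
                unknown += 1
    return {
        "trips_total": len(trips),
        "visits_by_category": by_cat,
        "visits_unknown": unknown,
    }


# --------------------------------------------------------------------------
# GPS validity gate
# --------------------------------------------------------------------------


def assess_gps_validity(
    report: DataLossReport,
    min_minutes_per_day: float = 480.0,
    min_valid_days: int = 5,
) -> tuple[bool, int]:
    """Inclusion gate: >= 480 recorded minutes on >= 5 monitoring days."""
    n_valid = sum(1 for m in report.per_day_minutes.values()
                  if m >= min_minutes_per_day)
    return n_valid >= min_valid_days, n_valid
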