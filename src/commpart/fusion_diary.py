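"""Fusion of GPS context with accelerometer epochs, diary-vs-GPS trip
matching within a temporal tolerance, and social-interaction tallies.

Fusion is total: every classified epoch receives exactly one context (home,
travel, a visit category, or unknown during ambiguous GPS gaps).  Diary
trips match GPS trips greedily in chronological order within a 10-minute
departure tolerance — transparent, and guarded by a property test against
the optimal assignment on small instances.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    CATEGORIES,
    CLASS_NAMES,
    MODERATE,
    SLEEP,
    VIGOROUS,
    DiaryEntry,
    EpochSeries,
    GpsTrack,
    MatchResult,
    TripEpisode,
)


# --------------------------------------------------------------------------
# GPS x accelerometer fusion
# --------------------------------------------------------------------------


def fuse(
    trips: list[TripEpisode],
    series: EpochSeries,
    track: GpsTrack | None = None,
    gap_min: float = 10.0,
) -> pd.DataFrame:
    """Label every classified epoch with its location context.

    Context is ``home`` outside any trip, a visit's category during the
    visit, ``travel`` inside a trip between visits (or the walk category for
    a visit-less walk loop).  Epochs during a GPS gap longer than
    ``gap_min`` inherit the surrounding context only if both gap ends agree,
    else ``unknown``.
    """
    if series.classes is None:
        raise ValueError("series must be classified before fusion")
    mids = series.midpoints
    if track is not None and track.n_fixes:
        t0 = max(series.timestamps[0], track.timestamps[0])
        t1 = min(
            series.timestamps[-1] + np.timedelta64(series.epoch_s, "s"),
            track.timestamps[-1],
        )
        if t0 >= t1:
            raise ValueError("GPS and accelerometer time ranges are disjoint")

    context = np.full(mids.size, "home", dtype=object)

    def stamp(a, b, label):
        context[(mids >= a) & (mids < b)] = label

    for t in trips:
        label = "local_walk_greenspace" if t.walk_loop else "travel"
        stamp(t.departure, t.return_, label)
        for v in t.visits:
            stamp(v.arrival, v.departure, v.category)

    def context_at(ts: np.datetime64) -> str:
        for t in trips:
            if t.departure <= ts < t.return_:
                for v in t.visits:
                    if v.arrival <= ts < v.departure:
                        return v.category
                return "local_walk_greenspace" if t.walk_loop else "travel"
        return "home"

    if track is not None and track.n_fixes > 1:
        gaps = np.flatnonzero(
            np.diff(track.timestamps) > np.timedelta64(int(gap_min * 60), "s")
        )
        for g in gaps:
            a, b = track.timestamps[g], track.timestamps[g + 1]
            if context_at(a) != context_at(b):
                stamp(a, b, "unknown")

    return pd.DataFrame(
        {
            "timestamp": series.timestamps,
            "class_code": series.classes,
            "cls": [CLASS_NAMES[c] for c in series.classes],
            "context": context,
            "span_s": series.spans,
        }
    )


def context_minutes(fused: pd.DataFrame) -> pd.DataFrame:
    """Minutes per (context, class) — the fused time-use table."""
    df = fused.assign(minutes=fused["span_s"] / 60.0)
    return df.pivot_table(
        index="context", columns="cls", values="minutes",
        aggfunc="sum", fill_value=0.0,
    )


def out_of_home_mvpa_min(fused: pd.DataFrame) -> float:
    """MVPA minutes accumulated away from home (travel or any visit)."""
    m = (
        ~fused["context"].isin(["home", "unknown"])
        & fused["class_code"].isin([MODERATE, VIGOROUS])
    )
    return float(fused.loc[m, "span_s"].sum() / 60.0)


# --------------------------------------------------------------------------
# Diary-trip vs GPS-trip matching
# --------------------------------------------------------------------------


@dataclass
class DiaryTrip:
    """An out-of-home diary entry treated as a reported trip."""

    index: int
    start: np.datetime64
    end: np.datetime64
    category: str
    social_interactions: int


def diary_trips(diary: list[DiaryEntry]) -> list[DiaryTrip]:
    """Out-of-home, non-sleep diary entries, time-sorted."""
    out = [
        DiaryTrip(i, e.start, e.end, e.reported_category, e.social_interactions)
        for i, e in enumerate(diary)
        if e.reported_category in CATEGORIES and not e.is_sleep
    ]
    out.sort(key=lambda t: t.start)
    return out


def match_diary_to_gps(
    diary: list[DiaryTrip],
    gps: list[TripEpisode],
    tolerance_min: float = 10.0,
) -> MatchResult:
    """Greedy chronological matching of reported trips to GPS trips.

    Each diary trip takes the earliest still-unmatched GPS trip whose
    departure lies within ``tolerance_min`` of the reported start; category
    agreement is recorded separately from the temporal match.
    """
    tol = np.timedelta64(int(round(tolerance_min * 60)), "s")
    gps_sorted = sorted(range(len(gps)), key=lambda j: gps[j].departure)
    used = set()
    pairs = []
    for d in sorted(diary, key=lambda t: t.start):
        for j in gps_sorted:
            if j in used:
                continue
            off = gps[j].departure - d.start
            if abs(off) <= tol:
                used.add(j)
                pairs.append(
                    (
                        d.index,
                        j,
                        float(off / np.timedelta64(60, "s")),
                        d.category == gps[j].primary_category(),
                    )
                )
                break

    self_counts = {c: 0 for c in CATEGORIES}
    for d in diary:
        self_counts[d.category] += 1
    gps_counts = {c: 0 for c in CATEGORIES}
    for t in gps:
        if t.walk_loop:
            gps_counts["local_walk_greenspace"] += 1
        for v in t.visits:
            if v.category in gps_counts:
                gps_counts[v.category] += 1
    return MatchResult(
        pairs=pairs,
        unmatched_diary=len(diary) - len(pairs),
        unmatched_gps=len(gps) - len(pairs),
        self_counts=self_counts,
        gps_counts=gps_counts,
    )


# --------------------------------------------------------------------------
# Social interactions
# --------------------------------------------------------------------------


@dataclass
class SocialTally:
    total: int
    in_home: int
    out_of_home: int
    by_category: dict


def tally_social(diary: list[DiaryEntry]) -> SocialTally:
    """Sum reported social interactions in-home, out-of-home and by venue."""
    by_cat = {c: 0 for c in CATEGORIES}
    in_home = 0
    for e in diary:
        if e.is_sleep:
            continue
        if e.reported_category == "home":
            in_home += e.social_interactions
        elif e.reported_category in by_cat:
            by_cat[e.reported_category] += e.social_interactions
    out = sum(by_cat.values())
    return SocialTally(
        total=in_home + out, in_home=in_home, out_of_home=out, by_category=by_cat
    )
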