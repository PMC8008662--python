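"""Accelerometer intensity metrics: cut-point classification, sleep
exclusion, daily intensity minutes, and valid-day gating.

Counts per 60-s epoch are classified with the wrist cut points light 283,
moderate 605 and vigorous 1697; a count at or above a threshold takes the
higher class.  For other epoch lengths the thresholds are scaled linearly
by ``epoch_s / 60`` — the simplest defensible adjustment for sampling
frequency and epoch length, and configurable because devices differ.
Sedentary is waking time below the light threshold (no separate sedentary
cut point is defined).  Sleep comes from diary windows and is excluded from
every intensity tally.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    LIGHT,
    MODERATE,
    SEDENTARY,
    SLEEP,
    VIGOROUS,
    AccelValidity,
    EpochSeries,
    floor_day,
    weekday,
)


@dataclass
class CutPoints:
    """Intensity thresholds in counts per reference epoch (default 60 s)."""

    light: float = 283.0
    moderate: float = 605.0
    vigorous: float = 1697.0
    reference_epoch_s: int = 60

    def __post_init__(self):
        if not (0 < self.light < self.moderate < self.vigorous):
            raise ValueError("cut points must satisfy 0 < light < moderate < vigorous")

    def scaled(self, epoch_s) -> tuple:
        """Thresholds linearly rescaled to an epoch length (or array of spans)."""
        f = np.asarray(epoch_s, dtype=float) / self.reference_epoch_s
        return self.light * f, self.moderate * f, self.vigorous * f


def aggregate_epochs(series: EpochSeries, target_epoch_s: int) -> EpochSeries:
    """Sum counts into longer epochs on a midnight-aligned grid.

    ``target_epoch_s`` must be a positive multiple of the source epoch.
    Partial head/tail windows are kept, with their actual coverage recorded
    in ``spans_s``.  Any prior classification is discarded (classify after
    aggregating).
    """
    if target_epoch_s <= 0 or target_epoch_s % series.epoch_s != 0:
        raise ValueError(
            f"target epoch ({target_epoch_s}s) must be a positive multiple of "
            f"the source epoch ({series.epoch_s}s)"
        )
    if target_epoch_s == series.epoch_s:
        return EpochSeries(
            participant_id=series.participant_id,
            start=series.start,
            epoch_s=series.epoch_s,
            counts=series.counts.copy(),
            spans_s=None if series.spans_s is None else series.spans.copy(),
        )
    day0 = floor_day(series.start)
    offs = ((series.timestamps - day0) / np.timedelta64(1, "s")).astype(np.int64)
    win = offs // target_epoch_s
    win -= win[0]
    n_win = int(win[-1]) + 1
    counts = np.zeros(n_win)
    np.add.at(counts, win, series.counts)
    spans = np.zeros(n_win)
    np.add.at(spans, win, series.spans)
    first_off = int(offs[0] - (offs[0] // target_epoch_s) * target_epoch_s)
    start = series.timestamps[0] - np.timedelta64(first_off, "s")
    # windows are contiguous because the source is; record partial coverage
    spans_s = None if np.all(spans == target_epoch_s) else spans
    return EpochSeries(
        participant_id=series.participant_id,
        start=start,
        epoch_s=target_epoch_s,
        counts=counts,
        spans_s=spans_s,
    )


def classify_intensity(series: EpochSeries, cuts: CutPoints | None = None) -> EpochSeries:
    """Assign sedentary/light/moderate/vigorous classes by scaled cut points.

    Boundary counts equal to a threshold take the higher class.  Epochs
    already masked as sleep are left untouched.
    """
    cuts = cuts or CutPoints()
    lo, mid, hi = cuts.scaled(series.spans)
    c = series.counts
    classes = np.full(series.n_epochs, SEDENTARY, dtype=np.int8)
    classes[c >= lo] = LIGHT
    classes[c >= mid] = MODERATE
    classes[c >= hi] = VIGOROUS
    if series.classes is not None:
        keep = series.classes == SLEEP
        classes[keep] = SLEEP
    return EpochSeries(
        participant_id=series.participant_id,
        start=series.start,
        epoch_s=series.epoch_s,
        counts=series.counts,
        classes=classes,
        spans_s=series.spans_s,
    )


def merge_windows(windows) -> list:
    """Merge overlapping/adjacent (start, end) windows."""
    ws = sorted((np.datetime64(a, "s"), np.datetime64(b, "s")) for a, b in windows)
    merged: list = []
    for a, b in ws:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def apply_sleep_mask(series: EpochSeries, sleep_windows) -> EpochSeries:
    """Mark epochs whose midpoint falls inside any sleep window as sleep.

    Overlapping windows are merged silently; masking is idempotent.
    """
    classes = (
        series.classes.copy()
        if series.classes is not None
        else np.full(series.n_epochs, SEDENTARY, dtype=np.int8)
    )
    mids = series.midpoints
    for a, b in merge_windows(sleep_windows):
        classes[(mids >= a) & (mids < b)] = SLEEP
    return EpochSeries(
        participant_id=series.participant_id,
        start=series.start,
        epoch_s=series.epoch_s,
        counts=series.counts,
        classes=classes,
        spans_s=series.spans_s,
    )


def daily_intensity_minutes(series: EpochSeries) -> pd.DataFrame:
    """Per-day minutes by class plus MVPA (moderate + vigorous).

    Waking minutes conserve: sedentary + light + moderate + vigorous.
    """
    if series.classes is None:
        raise ValueError("series must be classified first")
    dates = series.timestamps.astype("datetime64[D]")
    mins = series.spans / 60.0
    df = pd.DataFrame({"date": dates, "cls": series.classes, "min": mins})
    pivot = (
        df.pivot_table(index="date", columns="cls", values="min",
                       aggfunc="sum", fill_value=0.0)
        .reindex(columns=[SEDENTARY, LIGHT, MODERATE, VIGOROUS, SLEEP],
                 fill_value=0.0)
    )
    out = pd.DataFrame(
        {
            "sedentary_min": pivot[SEDENTARY],
            "light_min": pivot[LIGHT],
            "moderate_min": pivot[MODERATE],
            "vigorous_min": pivot[VIGOROUS],
            "sleep_min": pivot[SLEEP],
        }
    )
    out["mvpa_min"] = out["moderate_min"] + out["vigorous_min"]
    out["waking_min"] = (
        out["sedentary_min"] + out["light_min"] + out["mvpa_min"]
    )
    out.index.name = "date"
    return out


def assess_accel_validity(
    daily: pd.DataFrame,
    participant_id: str = "",
    min_waking_hours: float = 8.0,
    min_valid_days: int = 4,
    require_weekend: bool = True,
) -> AccelValidity:
    """Valid-day gate: >= 8 h recorded waking time on >= 4 days, at least one
    of them a weekend day."""
    waking = daily["waking_min"]
    valid = waking >= min_waking_hours * 60.0
    dates = daily.index.to_numpy().astype("datetime64[D]")
    wknd = weekday(dates) >= 5
    n_valid = int(valid.sum())
    has_wknd = bool(np.any(valid.to_numpy() & wknd))
    included = n_valid >= min_valid_days and (has_wknd or not require_weekend)
    return AccelValidity(
        participant_id=participant_id,
        per_day_waking_min={d: float(w) for d, w in zip(dates, waking)},
        valid_day={d: bool(v) for d, v in zip(dates, valid)},
        n_valid_days=n_valid,
        has_weekend_valid_day=has_wknd,
        included=included,
    )
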