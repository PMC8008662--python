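"""Reading and cleaning of GPS, accelerometer, diary, gazetteer and
covariate files, plus GPS data-completeness accounting.

GPS logger exports are cleaned of "title lines" — header text the device
re-emits whenever the signal was interrupted.  A title line is any data line
whose timestamp field does not parse as a datetime (the exact vendor header
text is not prescribed).  Fixes recorded before the monitoring start or
after its end are removed, duplicate timestamps collapse to the first
occurrence, and the cleaner reports how many lines it dropped.
"""
from __future__ import annotations

import csv
import json
import warnings
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CATEGORIES,
    DataLossReport,
    DiaryEntry,
    EpochSeries,
    Gazetteer,
    GeoFence,
    GpsTrack,
    as_dt64,
    floor_day,
)


class IngestError(ValueError):
    """Raised for unparseable files or schema violations (with row number)."""


def _parse_ts(text: str):
    try:
        return datetime.fromisoformat(text.strip())
    except (ValueError, TypeError):
        return None


def normalise_category(text: str) -> str:
    """Case-/punctuation-fold a reported location category.

    Accepts e.g. "Commercial", "local walk/greenspace", "CBD", "home".
    Raises IngestError for anything outside the closed vocabulary.
    """
    key = text.strip().lower().replace("/", "_").replace(" ", "_").replace("-", "_")
    while "__" in key:
        key = key.replace("__", "_")
    aliases = {
        "local_walk_greenspace": "local_walk_greenspace",
        "local_walk": "local_walk_greenspace",
        "greenspace": "local_walk_greenspace",
        "central_business_district": "cbd",
    }
    key = aliases.get(key, key)
    if key in CATEGORIES or key in ("home", "unknown"):
        return key
    raise IngestError(
        f"unknown location category {text!r}; allowed: "
        + ", ".join(CATEGORIES + ("home", "unknown"))
    )


# --------------------------------------------------------------------------
# GPS
# --------------------------------------------------------------------------


def read_gps(
    path,
    monitoring_start,
    monitoring_days: int,
    participant_id: str | None = None,
    nominal_epoch_s: int = 5,
) -> GpsTrack:
    """Read and clean one participant's GPS fixes from a CSV export.

    The file may contain several participants (``participant_id`` column);
    pass ``participant_id`` to select one.  Title lines are dropped and
    counted; fixes outside [monitoring_start, monitoring_start +
    monitoring_days) are trimmed; duplicates keep the first occurrence.
    """
    if monitoring_days < 1:
        raise ValueError("monitoring_days must be >= 1")
    start = as_dt64(monitoring_start)
    end = start + np.timedelta64(monitoring_days * 86400, "s")

    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise IngestError(f"{path}: empty file") from None
        cols = [h.strip().lower() for h in header]
        try:
            i_ts = cols.index("timestamp")
            i_lat = cols.index("lat")
            i_lon = cols.index("lon")
        except ValueError:
            raise IngestError(
                f"{path}: line 1: expected header with timestamp/lat/lon columns"
            ) from None
        i_pid = cols.index("participant_id") if "participant_id" in cols else None

        ts, lat, lon = [], [], []
        dropped = 0
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) <= max(i_ts, i_lat, i_lon) or _parse_ts(row[i_ts]) is None:
                dropped += 1  # title line: timestamp field does not parse
                continue
            if i_pid is not None and participant_id is not None:
                if row[i_pid].strip() != participant_id:
                    continue
            try:
                la, lo = float(row[i_lat]), float(row[i_lon])
            except ValueError:
                raise IngestError(
                    f"{path}: line {lineno}: bad coordinate value"
                ) from None
            ts.append(np.datetime64(_parse_ts(row[i_ts]), "s"))
            lat.append(la)
            lon.append(lo)

    if participant_id is None:
        participant_id = path.stem

    t = np.array(ts, dtype="datetime64[s]")
    la = np.array(lat, dtype=float)
    lo = np.array(lon, dtype=float)
    order = np.argsort(t, kind="stable")
    t, la, lo = t[order], la[order], lo[order]
    if t.size:
        uniq = np.concatenate(([True], np.diff(t) > np.timedelta64(0, "s")))
        t, la, lo = t[uniq], la[uniq], lo[uniq]
        keep = (t >= start) & (t < end)
        t, la, lo = t[keep], la[keep], lo[keep]
    if t.size == 0:
        warnings.warn(
            f"{participant_id}: no GPS fixes inside the monitoring window",
            stacklevel=2,
        )
    track = GpsTrack(
        participant_id=participant_id,
        timestamps=t,
        lat=la,
        lon=lo,
        nominal_epoch_s=nominal_epoch_s,
        dropped_title_lines=dropped,
    )
    track.validate()
    return track


def compute_data_loss(
    track: GpsTrack, monitoring_days: int, monitoring_start=None
) -> DataLossReport:
    """GPS completeness against the expected epoch-cell count.

    expected_cells = days * 86,400 / epoch (e.g. 120,960 for 7 days at 5 s);
    hours_lost = (expected - observed) * epoch / 3600.
    """
    eps = track.nominal_epoch_s
    if monitoring_start is None:
        if track.n_fixes == 0:
            raise ValueError("empty track needs an explicit monitoring_start")
        monitoring_start = floor_day(track.timestamps[0])
    start = as_dt64(monitoring_start)
    expected = monitoring_days * 86400 // eps

    per_day: dict = {}
    observed = 0
    if track.n_fixes:
        # distinct epoch cells actually covered
        cells = ((track.timestamps - start) / np.timedelta64(eps, "s")).astype(np.int64)
        cells = np.unique(cells[(cells >= 0) & (cells < expected)])
        observed = int(cells.size)
        day_idx = cells // (86400 // eps)
        for d in range(monitoring_days):
            date = (start + np.timedelta64(d * 86400, "s")).astype("datetime64[D]")
            per_day[date] = float(np.sum(day_idx == d) * eps / 60.0)
    else:
        for d in range(monitoring_days):
            date = (start + np.timedelta64(d * 86400, "s")).astype("datetime64[D]")
            per_day[date] = 0.0
    return DataLossReport(
        participant_id=track.participant_id,
        expected_cells=int(expected),
        observed_cells=observed,
        nominal_epoch_s=eps,
        per_day_minutes=per_day,
    )


# --------------------------------------------------------------------------
# Accelerometer
# --------------------------------------------------------------------------


def read_accel(path, participant_id: str | None = None) -> EpochSeries:
    """Read one participant's epoch-count series from accel.csv."""
    df = pd.read_csv(path)
    required = {"participant_id", "timestamp", "epoch_s", "count"}
    if not required.issubset(df.columns):
        raise IngestError(f"{path}: expected columns {sorted(required)}")
    if participant_id is not None:
        df = df[df["participant_id"] == participant_id]
    elif df["participant_id"].nunique() > 1:
        raise IngestError(f"{path}: multiple participants; pass participant_id")
    if df.empty:
        raise IngestError(f"{path}: no rows for participant {participant_id!r}")
    df = df.reset_index(drop=True)
    neg = df.index[df["count"] < 0]
    if len(neg):
        raise IngestError(f"{path}: row {int(neg[0]) + 2}: negative activity count")
    eps = int(df["epoch_s"].iloc[0])
    ts = pd.to_datetime(df["timestamp"]).to_numpy().astype("datetime64[s]")
    step = np.diff(ts) / np.timedelta64(1, "s")
    if ts.size > 1 and not np.all(step == eps):
        bad = int(np.flatnonzero(step != eps)[0]) + 3
        raise IngestError(f"{path}: row {bad}: epochs are not contiguous")
    series = EpochSeries(
        participant_id=participant_id or str(df["participant_id"].iloc[0]),
        start=ts[0],
        epoch_s=eps,
        counts=df["count"].to_numpy(float),
    )
    series.validate()
    return series


def participants_in(path) -> list[str]:
    """Participant ids present in a cohort CSV (any of the bundle files)."""
    df = pd.read_csv(path, usecols=["participant_id"])
    return list(pd.unique(df["participant_id"]))


# --------------------------------------------------------------------------
# Diary
# --------------------------------------------------------------------------


def read_diary(path, participant_id: str | None = None) -> list[DiaryEntry]:
    """Read diary entries; category strings are case-folded and validated."""
    df = pd.read_csv(path)
    required = {"participant_id", "start", "end", "activity", "category",
                "social_interactions", "is_sleep"}
    if not required.issubset(df.columns):
        raise IngestError(f"{path}: expected columns {sorted(required)}")
    if participant_id is not None:
        df = df[df["participant_id"] == participant_id]
    elif df["participant_id"].nunique() > 1:
        raise IngestError(f"{path}: multiple participants; pass participant_id")
    entries = []
    for i, row in df.reset_index(drop=True).iterrows():
        try:
            cat = normalise_category(str(row["category"]))
        except IngestError as err:
            raise IngestError(f"{path}: row {i + 2}: {err}") from None
        social = int(row["social_interactions"])
        if social < 0:
            raise IngestError(f"{path}: row {i + 2}: negative social_interactions")
        e = DiaryEntry(
            start=np.datetime64(pd.Timestamp(row["start"]).to_pydatetime(), "s"),
            end=np.datetime64(pd.Timestamp(row["end"]).to_pydatetime(), "s"),
            activity=str(row["activity"]),
            reported_category=cat,
            social_interactions=social,
            is_sleep=bool(int(row["is_sleep"])),
            is_nonwear=bool(int(row.get("is_nonwear", 0))),
        )
        try:
            e.validate()
        except ValueError as err:
            raise IngestError(f"{path}: row {i + 2}: {err}") from None
        entries.append(e)
    entries.sort(key=lambda e: e.start)
    return entries


def sleep_windows(diary: list[DiaryEntry]) -> list[tuple]:
    """(start, end) windows of diary-recorded sleep (and non-wear)."""
    return [(e.start, e.end) for e in diary if e.is_sleep or e.is_nonwear]


# --------------------------------------------------------------------------
# Gazetteer and covariates
# --------------------------------------------------------------------------


def read_gazetteer(path) -> Gazetteer:
    """Read the GeoJSON-like circular-geofence gazetteer."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise IngestError(f"{path}: not valid JSON: {err}") from None
    feats = []
    for i, f in enumerate(doc.get("features", [])):
        try:
            feats.append(
                GeoFence(
                    name=str(f.get("name", f"feature_{i}")),
                    lat=float(f["center"]["lat"]),
                    lon=float(f["center"]["lon"]),
                    radius_m=float(f["radius_m"]),
                    category=normalise_category(str(f["category"])),
                )
            )
        except (KeyError, TypeError, ValueError) as err:
            raise IngestError(f"{path}: feature {i}: {err}") from None
    gaz = Gazetteer(feats)
    gaz.validate()  # warns on overlap; raises on bad radius/category
    return gaz


def read_covariates(path) -> pd.DataFrame:
    """Covariate scores (HRQOL, loneliness, sleep quality, age) per participant."""
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise IngestError(f"{path}: expected a participant_id column")
    return df.set_index("participant_id")
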