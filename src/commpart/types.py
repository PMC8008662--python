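"""Shared data containers for the community-participation pipeline.

The containers mirror the measurement chain: GPS position fixes, epoch-level
accelerometer counts, diary entries, the geofence gazetteer, and the derived
trip / visit / agreement structures.  Timestamps are naive local datetimes
(``numpy.datetime64[s]``) throughout — the study design is single-timezone.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Closed vocabulary of out-of-home location categories.  The listing order
#: is meaningful: it is the deterministic tie-break order when a visit
#: centroid is equidistant from two geofence centres.
CATEGORIES: tuple[str, ...] = (
    "residential",
    "recreational",
    "commercial",
    "health",
    "local_walk_greenspace",
    "cbd",
    "place_of_worship",
)

# Intensity class codes stored in EpochSeries.classes (int8).
SEDENTARY, LIGHT, MODERATE, VIGOROUS, SLEEP = 0, 1, 2, 3, 4
UNCLASSIFIED = -1
CLASS_NAMES = {
    SEDENTARY: "sedentary",
    LIGHT: "light",
    MODERATE: "moderate",
    VIGOROUS: "vigorous",
    SLEEP: "sleep",
    UNCLASSIFIED: "unclassified",
}

_SEC = np.timedelta64(1, "s")


def as_dt64(value) -> np.datetime64:
    """Coerce a str/datetime/datetime64 to second-resolution datetime64."""
    return np.datetime64(value, "s")


def floor_day(ts) -> np.ndarray:
    """Local midnight of the day containing each timestamp."""
    return np.asarray(ts).astype("datetime64[D]").astype("datetime64[s]")


def weekday(dates) -> np.ndarray:
    """ISO weekday index (Monday=0 ... Sunday=6) for datetime64 values."""
    d = np.asarray(dates).astype("datetime64[D]").astype(np.int64)
    return (d + 3) % 7  # 1970-01-01 was a Thursday


@dataclass
class GpsFix:
    timestamp: np.datetime64
    lat: float
    lon: float


@dataclass
class GpsTrack:
    """Time-ordered GPS fixes for one participant, possibly with gaps."""

    participant_id: str
    timestamps: np.ndarray  # datetime64[s], strictly increasing
    lat: np.ndarray
    lon: np.ndarray
    nominal_epoch_s: int = 5
    #: timestamps of the first fix after each injected/observed dropout block
    resume_points: np.ndarray = field(
        default_factory=lambda: np.array([], dtype="datetime64[s]")
    )
    dropped_title_lines: int = 0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)

    def validate(self) -> None:
        if self.nominal_epoch_s <= 0:
            raise ValueError("nominal_epoch_s must be positive")
        if np.any(self.lat < -90) or np.any(self.lat > 90):
            raise ValueError("latitude out of range [-90, 90]")
        if np.any(self.lon < -180) or np.any(self.lon > 180):
            raise ValueError("longitude out of range [-180, 180]")
        if self.n_fixes > 1 and not np.all(np.diff(self.timestamps) > np.timedelta64(0, "s")):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_fixes(self) -> int:
        return int(self.timestamps.size)

    def fixes(self) -> list[GpsFix]:
        return [
            GpsFix(t, la, lo)
            for t, la, lo in zip(self.timestamps, self.lat, self.lon)
        ]


@dataclass
class EpochSeries:
    """Contiguous fixed-length accelerometer epochs for one participant.

    ``counts`` holds activity counts per epoch; ``classes`` is filled by
    intensity classification / sleep masking.  ``spans_s`` records the actual
    coverage of each epoch and differs from ``epoch_s`` only for a partial
    trailing (or leading) aggregation window.
    """

    participant_id: str
    start: np.datetime64  # [s]
    epoch_s: int
    counts: np.ndarray  # float
    classes: Optional[np.ndarray] = None  # int8 codes, see CLASS_NAMES
    spans_s: Optional[np.ndarray] = None

    def __post_init__(self):
        self.start = as_dt64(self.start)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.classes is not None:
            self.classes = np.asarray(self.classes, dtype=np.int8)

    def validate(self) -> None:
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be non-negative")

    @property
    def n_epochs(self) -> int:
        return int(self.counts.size)

    @property
    def timestamps(self) -> np.ndarray:
        """Epoch start times (contiguous grid from ``start``)."""
        return self.start + (np.arange(self.n_epochs) * self.epoch_s).astype(
            "timedelta64[s]"
        )

    @property
    def spans(self) -> np.ndarray:
        if self.spans_s is not None:
            return np.asarray(self.spans_s, dtype=float)
        return np.full(self.n_epochs, float(self.epoch_s))

    @property
    def midpoints(self) -> np.ndarray:
        return self.timestamps + (self.spans / 2.0).astype("timedelta64[s]")


@dataclass
class DiaryEntry:
    """One self-reported activity: time, place, social interactions."""

    start: np.datetime64
    end: np.datetime64
    activity: str
    reported_category: str  # a CATEGORIES value, "home", or "unknown"
    social_interactions: int = 0
    is_sleep: bool = False
    is_nonwear: bool = False

    def __post_init__(self):
        self.start = as_dt64(self.start)
        self.end = as_dt64(self.end)

    def validate(self) -> None:
        if not self.start < self.end:
            raise ValueError("diary entry must have start < end")
        if self.social_interactions < 0:
            raise ValueError("social_interactions must be >= 0")


@dataclass
class GeoFence:
    """A circular geofence carrying one of the closed location categories."""

    name: str
    lat: float
    lon: float
    radius_m: float
    category: str

    def validate(self) -> None:
        if self.radius_m <= 0:
            raise ValueError(f"geofence {self.name!r}: radius_m must be > 0")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"geofence {self.name!r}: unknown category {self.category!r}; "
                f"allowed: {', '.join(CATEGORIES)}"
            )


@dataclass
class Gazetteer:
    """Geofence -> category lookup replacing manual map inspection."""

    features: list[GeoFence]

    def validate(self) -> None:
        from .geo import haversine_m

        for f in self.features:
            f.validate()
        # Overlapping fences are legal (resolution happens at categorisation);
        # warn so the analyst knows ties will be broken by centre distance.
        for i, a in enumerate(self.features):
            for b in self.features[i + 1 :]:
                d = haversine_m(a.lat, a.lon, b.lat, b.lon)
                if d < a.radius_m + b.radius_m:
                    warnings.warn(
                        f"geofences {a.name!r} and {b.name!r} overlap; "
                        "visit categorisation will use the nearer centre",
                        stacklevel=2,
                    )

    def of_category(self, category: str) -> list[GeoFence]:
        return [f for f in self.features if f.category == category]


@dataclass
class DataLossReport:
    """GPS completeness accounting against the expected epoch-cell count."""

    participant_id: str
    expected_cells: int
    observed_cells: int
    nominal_epoch_s: int
    per_day_minutes: dict  # date (datetime64[D]) -> observed minutes

    @property
    def hours_lost(self) -> float:
        return (self.expected_cells - self.observed_cells) * self.nominal_epoch_s / 3600.0


@dataclass
class HomeAnchor:
    lat: float
    lon: float
    radius_m: float = 100.0


@dataclass
class LocationVisit:
    """A dwell-based stop within a trip, categorised via the gazetteer."""

    arrival: np.datetime64
    departure: np.datetime64
    lat: float
    lon: float
    category: str = "unknown"

    @property
    def dwell_min(self) -> float:
        return float((self.departure - self.arrival) / np.timedelta64(60, "s"))


@dataclass
class TripEpisode:
    """An out-of-home 'loop' beginning and ending at the home anchor."""

    departure: np.datetime64
    return_: np.datetime64
    visits: list[LocationVisit] = field(default_factory=list)
    complete_loop: bool = True
    walk_loop: bool = False  # visit-less neighbourhood loop, counted as local walk
    i0: int = -1  # index of first out-of-home fix in the source track
    i1: int = -1  # index of last out-of-home fix

    @property
    def duration_min(self) -> float:
        return float((self.return_ - self.departure) / np.timedelta64(60, "s"))

    def primary_category(self) -> str:
        if self.walk_loop:
            return "local_walk_greenspace"
        if self.visits:
            return self.visits[0].category
        return "unknown"


@dataclass
class AccelValidity:
    """Accelerometer valid-day gating (>=8 h waking; >=4 days incl. weekend)."""

    participant_id: str
    per_day_waking_min: dict  # date -> waking minutes recorded
    valid_day: dict  # date -> bool
    n_valid_days: int
    has_weekend_valid_day: bool
    included: bool


@dataclass
class MatchResult:
    """Diary-trip vs GPS-trip matching within a temporal tolerance."""

    pairs: list  # (diary_index, gps_index, offset_min, category_agreement)
    unmatched_diary: int
    unmatched_gps: int
    self_counts: dict  # category -> diary trip count
    gps_counts: dict  # category -> GPS visit count


@dataclass
class AgreementResult:
    """Paired self-report vs GPS comparison with Bland-Altman summary."""

    by: str
    n: int
    self_mean: float
    self_sd: float
    gps_mean: float
    gps_sd: float
    mean_diff: float  # self - gps
    t_stat: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    degenerate: bool
    pair_means: np.ndarray
    pair_diffs: np.ndarray


@dataclass
class Descriptives:
    """Median/IQR or mean/SD summary, branch chosen by a normality check."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    skew_z: float
    kurt_z: float
    normal: Optional[bool]
    branch: str  # "mean_sd" | "median_iqr" | "degenerate" | "insufficient"


@dataclass
class ParticipantSummary:
    """Per-participant participation metrics entering the cohort statistics."""

    participant_id: str
    trips_total: int
    visits_by_category: dict
    social_total: int
    social_in_home: int
    social_out_of_home: int
    social_by_category: dict
    mvpa_daily_mean: float
    hrqol: float
    loneliness: float
    sleep_quality: float
    age: float


@dataclass
class ParticipantBundle:
    """Everything recorded for one participant over the monitoring window."""

    participant_id: str
    gps: Optional[GpsTrack]
    accel: Optional[EpochSeries]
    diary: Optional[list]
    covariates: dict
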