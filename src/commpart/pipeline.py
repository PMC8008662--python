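"""End-to-end orchestration: simulate/load -> ingest -> accelerometer
metrics -> mobility -> diary fusion -> statistics, under one configuration.

Every threshold is echoed into the run report, participants failing any
validity gate are excluded with an explicit reason, and a rerun with the
same seed produces a byte-identical report hash.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import accel_metrics, fusion_diary, ingest, mobility, stats
from .types import (
    CATEGORIES,
    AccelValidity,
    DataLossReport,
    Gazetteer,
    ParticipantBundle,
    ParticipantSummary,
    as_dt64,
)

log = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Flat configuration for a pipeline run; round-trips through YAML."""

    monitoring_start: str = "2019-03-04T00:00:00"
    monitoring_days: int = Field(7, ge=1)
    gps_epoch_s: int = 5
    accel_target_epoch_s: int = 60
    assumed_utc_offset: str = "+09:30"  # documentation only; times stay naive

    # cut points (counts per 60-s epoch), scaled linearly to other epochs
    cut_light: float = 283.0
    cut_moderate: float = 605.0
    cut_vigorous: float = 1697.0

    # mobility thresholds (declared stand-ins; none are canonical)
    home_radius_m: float = 100.0
    min_trip_min: float = 5.0
    bridge_gap_min: float = 10.0
    dwell_radius_m: float = 50.0
    min_dwell_min: float = 5.0
    max_snap_m: float = 100.0
    neighbourhood_radius_m: float = 1000.0
    nocturnal_window: tuple[int, int] = (0, 6)
    explicit_homes: dict[str, tuple[float, float]] = Field(default_factory=dict)

    # validity gates
    gps_min_minutes_per_day: float = 480.0
    gps_min_valid_days: int = 5
    accel_min_waking_hours: float = 8.0
    accel_min_valid_days: int = 4
    accel_require_weekend: bool = True

    # fusion / matching / statistics
    tolerance_min: float = 10.0
    alpha_spearman: float = 0.01
    alpha_ttest: float = 0.05

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def cutpoints(self) -> accel_metrics.CutPoints:
        return accel_metrics.CutPoints(
            self.cut_light, self.cut_moderate, self.cut_vigorous
        )


@dataclass
class ParticipantResult:
    participant_id: str
    loss: Optional[DataLossReport]
    gps_included: bool
    gps_valid_days: int
    accel_validity: Optional[AccelValidity]
    diary_present: bool
    trips: list = field(default_factory=list)
    daily: Optional[pd.DataFrame] = None
    fused: Optional[pd.DataFrame] = None
    match: Optional[object] = None
    social: Optional[object] = None
    summary: Optional[ParticipantSummary] = None

    @property
    def accel_included(self) -> bool:
        return bool(self.accel_validity and self.accel_validity.included)


@dataclass
class RunResult:
    config: RunConfig
    ledger: pd.DataFrame
    participants: dict
    summaries: pd.DataFrame
    table3: Optional[stats.SpearmanMatrix]
    table4: Optional[pd.DataFrame]
    agreement: dict
    bland_altman: Optional[pd.DataFrame]
    report: dict

    @property
    def report_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.report, sort_keys=True, default=str).encode()
        ).hexdigest()


# --------------------------------------------------------------------------
# Per-participant processing
# --------------------------------------------------------------------------


def process_participant(
    bundle: ParticipantBundle, gazetteer: Gazetteer, config: RunConfig
) -> ParticipantResult:
    pid = bundle.participant_id
    log.info("%s: processing", pid)

    # --- GPS completeness and validity gate -------------------------------
    loss = None
    gps_ok, gps_days = False, 0
    if bundle.gps is not None and bundle.gps.n_fixes:
        loss = ingest.compute_data_loss(
            bundle.gps, config.monitoring_days, config.monitoring_start
        )
        gps_ok, gps_days = mobility.assess_gps_validity(
            loss, config.gps_min_minutes_per_day, config.gps_min_valid_days
        )

    # --- accelerometer metrics --------------------------------------------
    validity = None
    daily = None
    classified = None
    windows = ingest.sleep_windows(bundle.diary) if bundle.diary else []
    if bundle.accel is not None and bundle.accel.n_epochs:
        series = accel_metrics.aggregate_epochs(
            bundle.accel, config.accel_target_epoch_s
        )
        series = accel_metrics.apply_sleep_mask(series, windows)
        classified = accel_metrics.classify_intensity(series, config.cutpoints())
        daily = accel_metrics.daily_intensity_minutes(classified)
        validity = accel_metrics.assess_accel_validity(
            daily,
            pid,
            config.accel_min_waking_hours,
            config.accel_min_valid_days,
            config.accel_require_weekend,
        )

    # --- mobility ----------------------------------------------------------
    trips = []
    if bundle.gps is not None and bundle.gps.n_fixes:
        if pid in config.explicit_homes:
            lat, lon = config.explicit_homes[pid]
            home = mobility.HomeAnchor(lat, lon, config.home_radius_m)
        else:
            home = mobility.estimate_home(
                bundle.gps, config.nocturnal_window, radius_m=config.home_radius_m
            )
        trips = mobility.detect_trips(
            bundle.gps, home, config.min_trip_min, config.bridge_gap_min
        )
        for t in trips:
            t.visits = [
                mobility.categorize_visit(v, gazetteer, config.max_snap_m)
                for v in mobility.detect_visits(
                    t, bundle.gps, config.dwell_radius_m, config.min_dwell_min
                )
            ]
            t.walk_loop = mobility.classify_walk_loop(
                t, bundle.gps, home, config.neighbourhood_radius_m
            )

    # --- fusion and diary comparison ---------------------------------------
    fused = None
    if classified is not None and bundle.gps is not None and bundle.gps.n_fixes:
        fused = fusion_diary.fuse(
            trips, classified, bundle.gps, gap_min=config.bridge_gap_min
        )
    match = social = None
    if bundle.diary is not None:
        dtrips = fusion_diary.diary_trips(bundle.diary)
        match = fusion_diary.match_diary_to_gps(dtrips, trips, config.tolerance_min)
        social = fusion_diary.tally_social(bundle.diary)

    res = ParticipantResult(
        participant_id=pid,
        loss=loss,
        gps_included=gps_ok,
        gps_valid_days=gps_days,
        accel_validity=validity,
        diary_present=bundle.diary is not None,
        trips=trips,
        daily=daily,
        fused=fused,
        match=match,
        social=social,
    )

    if gps_ok and res.accel_included and res.diary_present:
        counts = mobility.count_participation(trips)
        valid_days = [d for d, ok in validity.valid_day.items() if ok]
        mvpa = float(
            daily.loc[daily.index.isin(valid_days), "mvpa_min"].mean()
        )
        res.summary = ParticipantSummary(
            participant_id=pid,
            trips_total=counts["trips_total"],
            visits_by_category=counts["visits_by_category"],
            social_total=social.total,
            social_in_home=social.in_home,
            social_out_of_home=social.out_of_home,
            social_by_category=social.by_category,
            mvpa_daily_mean=mvpa,
            hrqol=float(bundle.covariates.get("hrqol", np.nan)),
            loneliness=float(bundle.covariates.get("loneliness", np.nan)),
            sleep_quality=float(bundle.covariates.get("sleep_quality", np.nan)),
            age=float(bundle.covariates.get("age", np.nan)),
        )
    return res


# --------------------------------------------------------------------------
# Exclusion gate
# --------------------------------------------------------------------------


def exclusion_gate(results: list[ParticipantResult]) -> pd.DataFrame:
    """Validity ledger: inclusion requires GPS, accelerometer and diary."""
    rows = []
    for r in results:
        included = r.gps_included and r.accel_included and r.diary_present
        if r.gps_included is False:
            reason = "gps_days<5"
        elif not r.accel_included:
            reason = "accel_invalid"
        elif not r.diary_present:
            reason = "diary_missing"
        else:
            reason = ""
        rows.append(
            {
                "participant_id": r.participant_id,
                "gps_included": r.gps_included,
                "gps_valid_days": r.gps_valid_days,
                "accel_included": r.accel_included,
                "diary_present": r.diary_present,
                "included": included,
                "exclusion_reason": reason,
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


# --------------------------------------------------------------------------
# Cohort statistics and run report
# --------------------------------------------------------------------------


def _summaries_frame(results: list[ParticipantResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        if r.summary is None:
            continue
        s = r.summary
        row = {
            "participant_id": s.participant_id,
            "trips_total": s.trips_total,
            "social_interactions": s.social_total,
            "social_in_home": s.social_in_home,
            "social_out_of_home": s.social_out_of_home,
            "mvpa": s.mvpa_daily_mean,
            "hrqol": s.hrqol,
            "loneliness": s.loneliness,
            "sleep_quality": s.sleep_quality,
            "age": s.age,
        }
        for c in CATEGORIES:
            row[f"visits_{c}"] = s.visits_by_category.get(c, 0)
        rows.append(row)
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows).set_index("participant_id")


def run_pipeline(
    bundles: list[ParticipantBundle],
    gazetteer: Gazetteer,
    config: RunConfig,
) -> RunResult:
    """Run the full analysis over a cohort of bundles."""
    log.info("run start; thresholds: %s", config.model_dump())
    results = [process_participant(b, gazetteer, config) for b in bundles]
    ledger = exclusion_gate(results)
    included = {r.participant_id for r in results
                if ledger.loc[r.participant_id, "included"]}
    summaries = _summaries_frame([r for r in results
                                  if r.participant_id in included])

    table3 = table4 = bland = None
    agreement: dict = {}
    if len(summaries) >= 5:
        rows = ["trips_total"] + [f"visits_{c}" for c in CATEGORIES]
        cols = ["social_interactions", "mvpa", "hrqol", "loneliness", "sleep_quality"]
        table3 = stats.spearman_matrix(summaries, rows, cols,
                                       alpha=config.alpha_spearman)

    inc = [r for r in results if r.participant_id in included
           and r.match is not None]
    if len(inc) >= 2:
        self_rows, gps_rows = [], []
        for r in inc:
            m = r.match
            self_rows.append(
                {"total": sum(m.self_counts.values()), **m.self_counts}
            )
            gps_rows.append({"total": len(r.trips), **m.gps_counts})
        idx = [r.participant_id for r in inc]
        self_df = pd.DataFrame(self_rows, index=idx)
        gps_df = pd.DataFrame(gps_rows, index=idx)
        table4, agreement = stats.agreement_table(self_df, gps_df,
                                                  alpha=config.alpha_ttest)
        bland = stats.bland_altman_table(agreement["total"])

    report = _build_report(config, results, ledger, summaries, table4)
    return RunResult(
        config=config,
        ledger=ledger,
        participants={r.participant_id: r for r in results},
        summaries=summaries,
        table3=table3,
        table4=table4,
        agreement=agreement,
        bland_altman=bland,
        report=report,
    )


def _build_report(config, results, ledger, summaries, table4) -> dict:
    n_inc = int(ledger["included"].sum())
    losses = [r.loss for r in results if r.loss is not None]
    expected_h = sum(
        r.expected_cells * r.nominal_epoch_s / 3600.0 for r in losses
    )
    observed_h = sum(
        r.observed_cells * r.nominal_epoch_s / 3600.0 for r in losses
    )
    inc_losses = [
        r.loss for r in results
        if r.loss is not None and ledger.loc[r.participant_id, "included"]
    ]
    report = {
        "config": config.model_dump(),
        "n_participants": len(results),
        "n_included": n_inc,
        "exclusions": {
            pid: row["exclusion_reason"]
            for pid, row in ledger.iterrows()
            if not row["included"]
        },
        "gps_hours": {
            "expected_total": round(expected_h, 3),
            "observed_total": round(observed_h, 3),
            "expected_included": round(
                sum(r.expected_cells * r.nominal_epoch_s / 3600.0
                    for r in inc_losses), 3
            ),
            "mean_hours_lost_included": round(
                float(np.mean([r.hours_lost for r in inc_losses]))
                if inc_losses else float("nan"), 3
            ),
        },
    }
    if len(summaries):
        trips = stats.describe(summaries["trips_total"])
        mvpa = stats.describe(summaries["mvpa"])
        report["cohort"] = {
            "trips_median": trips.median,
            "trips_iqr": [trips.q1, trips.q3],
            "mvpa_median": mvpa.median,
            "mvpa_iqr": [mvpa.q1, mvpa.q3],
            "social_median": float(np.median(summaries["social_interactions"])),
        }
    if table4 is not None:
        report["agreement_total_mean_difference"] = float(
            table4.loc["total", "mean_difference"]
        )
    return report


# --------------------------------------------------------------------------
# Output writing
# --------------------------------------------------------------------------


def write_run(result: RunResult, out_dir) -> None:
    """Write all module outputs (CSV) and the JSON run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    result.ledger.to_csv(out / "validity_ledger.csv")
    if len(result.summaries):
        result.summaries.to_csv(out / "summaries.csv")

    trips_rows, visit_rows, daily_frames = [], [], []
    match_rows, social_rows = [], []
    for pid, r in result.participants.items():
        for k, t in enumerate(r.trips):
            trips_rows.append(
                {
                    "participant_id": pid,
                    "trip_idx": k,
                    "departure": t.departure,
                    "return": t.return_,
                    "n_visits": len(t.visits),
                    "complete_loop": t.complete_loop,
                    "walk_loop": t.walk_loop,
                }
            )
            for v in t.visits:
                visit_rows.append(
                    {
                        "participant_id": pid,
                        "trip_idx": k,
                        "arrival": v.arrival,
                        "departure": v.departure,
                        "lat": v.lat,
                        "lon": v.lon,
                        "category": v.category,
                    }
                )
        if r.daily is not None:
            d = r.daily.reset_index()
            d.insert(0, "participant_id", pid)
            if r.accel_validity is not None:
                d["valid_day"] = [
                    r.accel_validity.valid_day.get(np.datetime64(x, "D"), False)
                    for x in d["date"]
                ]
            daily_frames.append(d)
        if r.match is not None:
            for di, gi, off, agree in r.match.pairs:
                match_rows.append(
                    {
                        "participant_id": pid,
                        "diary_index": di,
                        "gps_trip_idx": gi,
                        "offset_min": off,
                        "category_agreement": agree,
                    }
                )
        if r.social is not None:
            for cat, nsoc in r.social.by_category.items():
                social_rows.append(
                    {"participant_id": pid, "category": cat, "interactions": nsoc}
                )
            social_rows.append(
                {"participant_id": pid, "category": "home",
                 "interactions": r.social.in_home}
            )

    pd.DataFrame(trips_rows).to_csv(out / "trips.csv", index=False)
    pd.DataFrame(visit_rows).to_csv(out / "visits.csv", index=False)
    if daily_frames:
        pd.concat(daily_frames).to_csv(out / "daily_metrics.csv", index=False)
    pd.DataFrame(match_rows).to_csv(out / "matches.csv", index=False)
    pd.DataFrame(social_rows).to_csv(out / "social.csv", index=False)

    if result.table3 is not None:
        result.table3.annotated().to_csv(out / "table3.csv")
    if result.table4 is not None:
        result.table4.to_csv(out / "table4.csv")
    if result.bland_altman is not None:
        result.bland_altman.to_csv(out / "blandaltman.csv", index=False)

    report = dict(result.report)
    report["report_hash"] = result.report_hash
    (out / "run_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=str)
    )
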