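"""Shared fixtures: ground-truthed synthetic cohorts at several scales.

Cohorts are session-scoped because generation dominates test runtime; every
test works from the same frozen seeds, so results are reproducible.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import commpart as cp

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_profile_small() -> cp.SimProfile:
    """A loss-free, jitter-free, no-over-report cohort of 6 participants."""
    return cp.SimProfile(
        n_participants=6,
        days=7,
        seed=11,
        gps_loss_hours_mean=0.0,
        diary_overreport_rate=0.0,
        diary_jitter_min=0.0,
    )


@pytest.fixture(scope="session")
def clean_cohort_small(clean_profile_small):
    return cp.generate_cohort(clean_profile_small)


@pytest.fixture(scope="session")
def clean_run_small(clean_cohort_small):
    bundles, truth, gaz = clean_cohort_small
    return cp.run_pipeline(bundles, gaz, cp.RunConfig(seed=11)), truth


@pytest.fixture(scope="session")
def cohort44_clean():
    """Loss-free, jitter-free n=44 cohort for exact-recovery checks."""
    prof = cp.SimProfile(
        n_participants=44,
        days=7,
        seed=1,
        gps_loss_hours_mean=0.0,
        diary_overreport_rate=0.0,
        diary_jitter_min=0.0,
    )
    return cp.generate_cohort(prof)


@pytest.fixture(scope="session")
def run44_clean(cohort44_clean):
    bundles, truth, gaz = cohort44_clean
    return cp.run_pipeline(bundles, gaz, cp.RunConfig(seed=1)), truth


@pytest.fixture(scope="session")
def cohort44_lossy():
    """n=44 under the default study conditions (9.3 h mean GPS loss)."""
    prof = cp.SimProfile(n_participants=44, days=7, seed=1)
    return cp.generate_cohort(prof)


@pytest.fixture(scope="session")
def run44_lossy(cohort44_lossy):
    bundles, truth, gaz = cohort44_lossy
    return cp.run_pipeline(bundles, gaz, cp.RunConfig(seed=1)), truth


@pytest.fixture(scope="session")
def cohort200():
    """n=200 cohort under default conditions for structural recovery."""
    prof = cp.SimProfile(n_participants=200, days=7, seed=7)
    return cp.generate_cohort(prof)


@pytest.fixture(scope="session")
def run200(cohort200):
    bundles, truth, gaz = cohort200
    return cp.run_pipeline(bundles, gaz, cp.RunConfig(seed=7)), truth


def true_mvpa_minutes(truth_p) -> float:
    """Oracle: ground-truth MVPA minutes from the per-minute class array."""
    from commpart.types import MODERATE, VIGOROUS

    cls = truth_p.minute_classes
    return float(np.sum((cls == MODERATE) | (cls == VIGOROUS)))
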