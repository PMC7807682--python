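"""Shared fixtures: hand-built epoch series and a reusable synthetic cohort."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from actibed.epoch_io import DiaryDay, EpochSeries
from actibed.pipeline import build_analysis_table
from actibed.synthetic import CohortConfig, generate_cohort

START = pd.Timestamp("2013-05-06 00:00")


def make_series(counts, start=START, pid="P1") -> EpochSeries:
    return EpochSeries(participant_id=pid, start=start, counts=np.asarray(counts, float))


def build_fixture_days(
    n_days: int,
    bed_clock: dt.time,
    rise_clock: dt.time,
    first_date: dt.date = dt.date(2013, 5, 6),
    pid_naps=(),
) -> list[DiaryDay]:
    """Nightly diary with identical bed/rise clock times each day."""
    days = []
    for d in range(n_days):
        night = first_date + dt.timedelta(days=d)
        bed = pd.Timestamp.combine(night, bed_clock)
        if rise_clock <= bed_clock:
            rise = pd.Timestamp.combine(night + dt.timedelta(days=1), rise_clock)
        else:
            rise = pd.Timestamp.combine(night, rise_clock)
        days.append(DiaryDay(date=night, bed_time=bed, rise_time=rise, naps=pid_naps))
    return days


def constant_day_counts(
    n_days: int,
    wear_value: float,
    bed_clock: dt.time,
    rise_clock: dt.time,
) -> np.ndarray:
    """Counts that are ``wear_value`` while out of bed and 0 while in bed.

    The in-bed interval runs from ``bed_clock`` (evening) to ``rise_clock``
    (next morning); the first morning (before the first night's rise) is
    also zero, mimicking sleep carried over from before the recording.
    """
    n = n_days * 1440
    counts = np.full(n, float(wear_value))
    bed_min = bed_clock.hour * 60 + bed_clock.minute
    rise_min = rise_clock.hour * 60 + rise_clock.minute
    counts[:rise_min] = 0.0  # residual sleep of the unrecorded night
    for d in range(n_days):
        i = d * 1440 + bed_min
        j = (d + 1) * 1440 + rise_min
        counts[i : min(j, n)] = 0.0
    return counts


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_participants=60, seed=42))


@pytest.fixture(scope="session")
def analysis_table(small_cohort):
    table, _ = build_analysis_table(small_cohort)
    return table
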