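"""Windowed daily and person-level physical-activity / sedentary exposures.

Counts are classified with wrist vector-magnitude cut-points for older
adults: sedentary behaviour (SB) 0–2302 cpm, and two relative-intensity
bands 2303–4999 and >= 5000 cpm (no validated moderate/vigorous cut-points
exist for the wrist, so the upper bands describe *relatively* higher
intensity, not MVPA).

Summaries are restricted to wear time inside the 05:00–24:00 window
(maximum 19 h/day); night epochs are excluded because in this age group
they mostly reflect time in bed or restlessness.  A day is valid with at
least 10 h (600 min) of wear, a participant with at least 4 valid days.
Band occupancy is expressed as percent of wear time; the person level pools
epochs across valid days (total band minutes over total wear minutes)
rather than averaging daily percentages, with the alternative available via
``pooling="mean_of_days"``.  A participant is *highly sedentary* when the
pooled SB share is >= 65 % of wear time (about 10 h/day at the typical
15.5-h wear day of this population).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .epoch_io import DiaryDay, EpochSeries
from .nonwear import WEAR, WearMask

__all__ = [
    "IntensityBands",
    "DailySummary",
    "ParticipantExposure",
    "ExclusionError",
    "classify_intensity",
    "daily_summaries",
    "participant_exposure",
    "tertile_assign",
]


class ExclusionError(ValueError):
    """Participant cannot contribute exposures; carries the logged reason."""


@dataclass(frozen=True)
class IntensityBands:
    """Cut-points, summarization window and validity thresholds."""

    sb_upper: int = 2302              # SB is 0..sb_upper cpm, inclusive
    mid_upper: int = 4999             # mid band is sb_upper+1..mid_upper
    window_start: dt.time = dt.time(5, 0)
    window_end: dt.time = dt.time(0, 0)   # midnight == 24:00, exclusive
    min_wear: int = 600               # minutes/day for a valid day
    min_valid_days: int = 4
    highly_sedentary_threshold: float = 0.65  # fraction of wear time
    fixed_sleep_window: tuple[dt.time, dt.time] = (dt.time(23, 0), dt.time(8, 0))

    def __post_init__(self) -> None:
        if not 0 < self.sb_upper < self.mid_upper:
            raise ValueError("need 0 < sb_upper < mid_upper")
        if not 0 < self.highly_sedentary_threshold < 1:
            raise ValueError("highly_sedentary_threshold must be in (0, 1)")

    @property
    def window_minutes(self) -> int:
        start = self.window_start.hour * 60 + self.window_start.minute
        end = self.window_end.hour * 60 + self.window_end.minute
        if end == 0:
            end = 24 * 60
        return end - start


@dataclass(frozen=True)
class DailySummary:
    """One calendar day's wear time and band occupancy.

    Percentages are of wear time and are NaN when the day has no wear.
    """

    date: dt.date
    wear_minutes: int
    avg_cpm: float
    pct_sb: float
    pct_mid: float
    pct_high: float
    valid: bool


@dataclass(frozen=True)
class ParticipantExposure:
    """Person-level exposures pooled over valid days."""

    avg_cpm: float
    pct_sb: float
    pct_mid: float
    pct_high: float
    highly_sedentary: bool
    avg_nap_minutes: float
    n_valid_days: int


def classify_intensity(cpm: float, bands: IntensityBands = IntensityBands()) -> str:
    """Classify a single epoch count into SB / MID / HIGH."""
    if cpm < 0:
        raise ValueError(f"counts must be non-negative, got {cpm}")
    if cpm <= bands.sb_upper:
        return "SB"
    if cpm <= bands.mid_upper:
        return "MID"
    return "HIGH"


def _in_window(ts: pd.DatetimeIndex, bands: IntensityBands) -> np.ndarray:
    minutes = ts.hour * 60 + ts.minute
    start = bands.window_start.hour * 60 + bands.window_start.minute
    end = bands.window_end.hour * 60 + bands.window_end.minute
    if end == 0:
        end = 24 * 60
    return (minutes >= start) & (minutes < end)


def daily_summaries(
    series: EpochSeries,
    mask: WearMask,
    bands: IntensityBands = IntensityBands(),
) -> list[DailySummary]:
    """Summarize each calendar day of the recording.

    Only WEAR epochs with an observed count and a start time inside the
    summarization window contribute.  ``avg_cpm`` divides total counts by
    wear minutes; band percentages use wear minutes as denominator.  Days
    with fewer than ``min_wear`` wear minutes are flagged invalid.
    """
    if len(mask) != len(series):
        raise ValueError("mask is not aligned with series")
    ts = series.timestamps
    counts = series.counts
    contributes = (
        (mask.labels == WEAR) & ~np.isnan(counts) & _in_window(ts, bands)
    )
    days = ts.normalize()
    out: list[DailySummary] = []
    for day in days.unique():
        sel = contributes & (days == day)
        wear = int(sel.sum())
        if wear == 0:
            out.append(
                DailySummary(
                    date=day.date(), wear_minutes=0, avg_cpm=float("nan"),
                    pct_sb=float("nan"), pct_mid=float("nan"),
                    pct_high=float("nan"), valid=False,
                )
            )
            continue
        c = counts[sel]
        out.append(
            DailySummary(
                date=day.date(),
                wear_minutes=wear,
                avg_cpm=float(c.sum() / wear),
                pct_sb=float(100.0 * (c <= bands.sb_upper).sum() / wear),
                pct_mid=float(
                    100.0
                    * ((c > bands.sb_upper) & (c <= bands.mid_upper)).sum()
                    / wear
                ),
                pct_high=float(100.0 * (c > bands.mid_upper).sum() / wear),
                valid=wear >= bands.min_wear,
            )
        )
    return out


def participant_exposure(
    summaries: Sequence[DailySummary],
    diary: Sequence[DiaryDay],
    bands: IntensityBands = IntensityBands(),
    pooling: str = "pooled",
) -> ParticipantExposure:
    """Pool valid days into person-level exposures.

    Raises :class:`ExclusionError` when fewer than ``min_valid_days`` days
    are valid.  ``pooling="pooled"`` (default) divides total counts and
    total band minutes by total wear minutes; ``"mean_of_days"`` averages
    the daily values instead.
    """
    if not summaries:
        raise ExclusionError("no daily summaries")
    valid = [s for s in summaries if s.valid]
    if len(valid) < bands.min_valid_days:
        raise ExclusionError(
            f"only {len(valid)} valid days "
            f"(minimum {bands.min_valid_days} days of >= {bands.min_wear} min wear)"
        )
    if pooling == "pooled":
        wear = np.array([s.wear_minutes for s in valid], dtype=float)
        total = wear.sum()
        avg_cpm = float(sum(s.avg_cpm * s.wear_minutes for s in valid) / total)
        pct_sb = float(sum(s.pct_sb * s.wear_minutes for s in valid) / total)
        pct_mid = float(sum(s.pct_mid * s.wear_minutes for s in valid) / total)
        pct_high = float(sum(s.pct_high * s.wear_minutes for s in valid) / total)
    elif pooling == "mean_of_days":
        avg_cpm = float(np.mean([s.avg_cpm for s in valid]))
        pct_sb = float(np.mean([s.pct_sb for s in valid]))
        pct_mid = float(np.mean([s.pct_mid for s in valid]))
        pct_high = float(np.mean([s.pct_high for s in valid]))
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    nap = (
        float(np.mean([d.nap_minutes for d in diary])) if diary else 0.0
    )
    return ParticipantExposure(
        avg_cpm=avg_cpm,
        pct_sb=pct_sb,
        pct_mid=pct_mid,
        pct_high=pct_high,
        highly_sedentary=pct_sb >= 100.0 * bands.highly_sedentary_threshold,
        avg_nap_minutes=nap,
        n_valid_days=len(valid),
    )


def tertile_assign(values: Sequence[float]) -> list[str]:
    """Assign low/middle/high tertile labels by empirical 1/3–2/3 quantiles.

    Quantiles use inclusive linear interpolation; values equal to a cut
    point go to the lower tertile, which makes the assignment deterministic
    and stable under permutation of the input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 values for tertiles")
    if np.ptp(arr) == 0:
        raise ValueError("all values identical; tertiles are degenerate")
    q1, q2 = np.quantile(arr, [1 / 3, 2 / 3], method="linear")
    labels = np.where(arr <= q1, "low", np.where(arr <= q2, "middle", "high"))
    return labels.tolist()
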