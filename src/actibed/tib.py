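"""Nightly time in bed (TIB) and the UTIB/STIB/RTIB categorization.

TIB is the diary interval from going to bed until getting out of bed the
next day — it includes wakeful lying, not just sleep.  For adults 75+ a
nightly TIB of 7–9 h is taken as the appropriate range (sleep-onset latency
increases with age, so the range sits above the usual 7–8 h sleep
recommendation).  Participants are then categorized by how often their
nights fall in range:

* UTIB — usually in range: >= 80 % of measurement days
* STIB — sometimes: 20–79 % (implemented as [20 %, 80 %) so the three
  intervals tile [0, 100] exactly; the printed 79 is integer-percent
  shorthand that would leave gaps for e.g. 7-night denominators)
* RTIB — rarely: < 20 %

The denominator is the number of nights with a complete diary entry, not a
fixed 7.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .epoch_io import DiaryDay, LATE_BEDTIME_CUTOFF

__all__ = [
    "TibCategoryRule",
    "nightly_tib",
    "in_range",
    "categorize",
    "assign_tib_category",
    "diary_timing_summary",
]

CATEGORIES = ("UTIB", "STIB", "RTIB")


@dataclass(frozen=True)
class TibCategoryRule:
    """Thresholds of the TIB categorization.

    range_low/range_high : the appropriate nightly TIB range, hours
                           (closed on both ends; default 7–9 h)
    utib_min             : minimum percent of nights in range for UTIB (80)
    rtib_max             : percent of nights below which RTIB applies (20)
    """

    range_low: float = 7.0
    range_high: float = 9.0
    utib_min: float = 80.0
    rtib_max: float = 20.0

    def __post_init__(self) -> None:
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be < range_high")
        if not 0 < self.rtib_max < self.utib_min < 100:
            raise ValueError("need 0 < rtib_max < utib_min < 100")


def nightly_tib(diary_day: DiaryDay) -> float:
    """Minutes from going to bed until getting out of bed the next day."""
    return diary_day.tib_minutes


def in_range(tib_minutes: float, rule: TibCategoryRule = TibCategoryRule()) -> bool:
    """Whether a night's TIB falls in the appropriate range (inclusive)."""
    if tib_minutes <= 0:
        raise ValueError(f"tib_minutes must be positive, got {tib_minutes}")
    return rule.range_low * 60 <= tib_minutes <= rule.range_high * 60


def categorize(
    nights_in_range: int,
    nights_total: int,
    rule: TibCategoryRule = TibCategoryRule(),
) -> str:
    """Assign UTIB/STIB/RTIB from the share of nights in range.

    Exactly one category for any ``0 <= nights_in_range <= nights_total``
    with at least one night: UTIB iff the share is >= 80 %, RTIB iff < 20 %,
    STIB otherwise.
    """
    if nights_total < 1:
        raise ValueError("cannot categorize a participant with no diary nights")
    if not 0 <= nights_in_range <= nights_total:
        raise ValueError("nights_in_range must be between 0 and nights_total")
    p = 100.0 * nights_in_range / nights_total
    if p >= rule.utib_min:
        return "UTIB"
    if p < rule.rtib_max:
        return "RTIB"
    return "STIB"


def assign_tib_category(
    diary: Sequence[DiaryDay], rule: TibCategoryRule = TibCategoryRule()
) -> tuple[str, int, int]:
    """Categorize a participant from their diary.

    Returns ``(category, nights_in_range, nights_total)``.
    """
    nights = [nightly_tib(d) for d in diary]
    n_in = sum(in_range(t, rule) for t in nights)
    return categorize(n_in, len(nights), rule), n_in, len(nights)


def diary_timing_summary(diaries: Sequence[Sequence[DiaryDay]]) -> dict[str, float]:
    """Cohort-level timing of diary bed and rise times.

    Counts, over all diary days, the nights whose bed time and whose rise
    time fall in the late window 24:00–05:00, and their percentages of all
    diary days.
    """
    n_days = sum(len(d) for d in diaries)
    late_bed = sum(
        1
        for days in diaries
        for d in days
        if d.bed_time.time() < LATE_BEDTIME_CUTOFF
    )
    late_rise = sum(
        1
        for days in diaries
        for d in days
        if d.rise_time.time() < LATE_BEDTIME_CUTOFF
    )
    return {
        "n_diary_days": n_days,
        "n_late_bedtimes": late_bed,
        "n_late_risetimes": late_rise,
        "pct_late_bedtimes": 100.0 * late_bed / n_days if n_days else float("nan"),
        "pct_late_risetimes": 100.0 * late_rise / n_days if n_days else float("nan"),
    }
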