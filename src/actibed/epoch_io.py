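"""Read/write the epoch-count, diary, and covariate CSV dialects.

This module fixes the timestamp conventions used everywhere else:

* Epochs are half-open minutes ``[t, t + 60 s)``; an epoch belongs to a
  calendar day by its *start* time.
* An epoch is "inside" a diary interval when its start time is >= the
  interval start and < the interval end (half-open), so boundary minutes
  are never double counted.
* A diary "night" is identified by the date of the evening on which it
  starts.  Bed times with a clock time in ``[00:00, 05:00)`` are late
  bedtimes of the *previous* night: a row dated ``d`` with bed time 00:30
  yields a :class:`DiaryDay` for date ``d - 1``.

File dialects (UTF-8, comma-delimited, mandatory header):

* epoch CSV      — ``participant_id,timestamp,vm_cpm`` with ISO-8601 minute
  timestamps; an empty ``vm_cpm`` field marks a missing epoch.
* diary CSV      — ``participant_id,date,bed_time,rise_time`` plus optional
  ``nap<i>_start,nap<i>_end`` clock-time pairs.
* covariates CSV — ``participant_id,age,sex,sppb_total``.

Raw ActiGraph formats (.gt3x / ActiLife .agd) are *not* read here: count
generation happens upstream in device software, and this pipeline starts at
the per-minute vector-magnitude epoch counts.  See :func:`read_gt3x` for the
documented stub.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "DiaryDay",
    "FormatError",
    "read_epochs",
    "write_epochs",
    "read_diary",
    "write_diary",
    "read_covariates",
    "write_covariates",
    "read_gt3x",
    "LATE_BEDTIME_CUTOFF",
]

#: Clock time below which a bed time is attached to the preceding night.
LATE_BEDTIME_CUTOFF = dt.time(5, 0)

EPOCH_SECONDS = 60


class FormatError(ValueError):
    """A file violates the epoch/diary/covariate CSV contract."""


@dataclass(frozen=True)
class EpochSeries:
    """One participant's contiguous per-minute vector-magnitude counts.

    ``counts`` is a float array: non-negative integers for observed epochs
    and NaN for explicitly-missing epochs.  Epochs are contiguous; missing
    data is represented by NaN, never by absent rows.
    """

    participant_id: str
    start: pd.Timestamp
    counts: np.ndarray

    def __post_init__(self) -> None:
        start = pd.Timestamp(self.start)
        if start.second or start.microsecond or start.nanosecond:
            raise FormatError(f"series start {start} is not minute-aligned")
        counts = np.asarray(self.counts, dtype=float)
        observed = counts[~np.isnan(counts)]
        if (observed < 0).any():
            raise FormatError("negative count in epoch series")
        if observed.size and (observed != np.round(observed)).any():
            raise FormatError("non-integer count in epoch series")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.counts), freq="min")

    @property
    def end(self) -> pd.Timestamp:
        """Exclusive end of the recording (start of the epoch after the last)."""
        return self.start + pd.Timedelta(minutes=len(self.counts))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSeries):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.start == other.start
            and len(self.counts) == len(other.counts)
            and bool(
                np.array_equal(self.counts, other.counts, equal_nan=True)
            )
        )


@dataclass(frozen=True)
class DiaryDay:
    """One diary night: bed time, next rise time, and that day's naps.

    ``date`` is the evening on which the night starts; ``bed_time`` may fall
    after midnight (on ``date + 1``).  Naps are half-open timestamp pairs
    within the waking part of the day.
    """

    date: dt.date
    bed_time: pd.Timestamp
    rise_time: pd.Timestamp
    naps: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bed = pd.Timestamp(self.bed_time)
        rise = pd.Timestamp(self.rise_time)
        if rise <= bed:
            raise FormatError(
                f"rise_time {rise} not after bed_time {bed} on {self.date}"
            )
        naps = tuple((pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.naps)
        for a, b in naps:
            if b <= a:
                raise FormatError(f"nap end {b} not after start {a}")
        for (a1, b1), (a2, b2) in zip(naps, naps[1:]):
            if a2 < b1:
                raise FormatError(f"overlapping naps at {a2} on {self.date}")
        object.__setattr__(self, "bed_time", bed)
        object.__setattr__(self, "rise_time", rise)
        object.__setattr__(self, "naps", naps)

    @property
    def tib_minutes(self) -> float:
        return (self.rise_time - self.bed_time).total_seconds() / 60.0

    @property
    def nap_minutes(self) -> float:
        return sum((b - a).total_seconds() / 60.0 for a, b in self.naps)


# ---------------------------------------------------------------------------
# epoch CSV


def read_epochs(path: str | Path) -> EpochSeries:
    """Read one participant's epoch CSV into a contiguous minute series.

    Out-of-order rows are sorted; duplicate timestamps, negative counts and
    gaps in the minute grid are format errors.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "timestamp", "vm_cpm"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"epoch CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        # header-only file: an empty series (participant unknown)
        return EpochSeries(
            participant_id="", start=pd.Timestamp(0), counts=np.empty(0)
        )
    ids = df["participant_id"].unique()
    if len(ids) != 1:
        raise FormatError(f"epoch CSV contains multiple participants: {ids}")
    ts = pd.to_datetime(df["timestamp"])
    df = df.assign(timestamp=ts).sort_values("timestamp", kind="stable")
    dup = df["timestamp"].duplicated()
    if dup.any():
        raise FormatError(f"duplicate timestamp {df['timestamp'][dup].iloc[0]}")
    t = df["timestamp"].reset_index(drop=True)
    step = t.diff().dropna()
    bad = step != pd.Timedelta(minutes=1)
    if bad.any():
        first = t[1:][bad.to_numpy()].iloc[0] - pd.Timedelta(minutes=1)
        raise FormatError(f"gap in timestamps: missing epoch at {first}")
    counts = pd.to_numeric(df["vm_cpm"]).to_numpy(dtype=float)
    if np.nanmin(counts, initial=0) < 0:
        raise FormatError("negative count in epoch CSV")
    return EpochSeries(participant_id=str(ids[0]), start=t.iloc[0], counts=counts)


def write_epochs(series: EpochSeries, path: str | Path) -> None:
    """Write an :class:`EpochSeries` to epoch CSV (lossless round trip)."""
    vm = pd.array(series.counts, dtype="Int64")
    df = pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M"),
            "vm_cpm": vm,
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# diary CSV


def _parse_clock(value: str) -> dt.time:
    return dt.datetime.strptime(str(value).strip(), "%H:%M").time()


def read_diary(path: str | Path) -> dict[str, list[DiaryDay]]:
    """Read a diary CSV into per-participant lists of :class:`DiaryDay`.

    Row convention: ``date`` is the calendar day on which the bed time's
    clock reading occurs.  Bed times in [00:00, 05:00) are late bedtimes and
    are attached to the preceding night, so such a row dated ``d`` produces
    a DiaryDay for ``d - 1``.  Rise times always fall on the morning after
    the night; naps on the row's waking day.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "date", "bed_time", "rise_time"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"diary CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    nap_cols = []
    i = 1
    while f"nap{i}_start" in df.columns and f"nap{i}_end" in df.columns:
        nap_cols.append((f"nap{i}_start", f"nap{i}_end"))
        i += 1
    out: dict[str, list[DiaryDay]] = {}
    for _, row in df.iterrows():
        row_date = pd.Timestamp(row["date"]).date()
        bed_clock = _parse_clock(row["bed_time"])
        rise_clock = _parse_clock(row["rise_time"])
        if bed_clock < LATE_BEDTIME_CUTOFF:
            # late bedtime: the night belongs to the previous evening
            night = row_date - dt.timedelta(days=1)
            bed = pd.Timestamp.combine(row_date, bed_clock)
            rise = pd.Timestamp.combine(row_date, rise_clock)
        else:
            night = row_date
            bed = pd.Timestamp.combine(row_date, bed_clock)
            rise = pd.Timestamp.combine(row_date + dt.timedelta(days=1), rise_clock)
        naps = []
        for cs, ce in nap_cols:
            if pd.isna(row.get(cs)) or pd.isna(row.get(ce)):
                continue
            a = pd.Timestamp.combine(night, _parse_clock(row[cs]))
            b = pd.Timestamp.combine(night, _parse_clock(row[ce]))
            naps.append((a, b))
        day = DiaryDay(date=night, bed_time=bed, rise_time=rise, naps=tuple(naps))
        out.setdefault(str(row["participant_id"]), []).append(day)
    for days in out.values():
        days.sort(key=lambda d: d.date)
    return out


def write_diary(
    diaries: dict[str, Sequence[DiaryDay]], path: str | Path
) -> None:
    """Write per-participant diaries to diary CSV (inverse of read_diary)."""
    max_naps = max(
        (len(d.naps) for days in diaries.values() for d in days), default=0
    )
    cols = ["participant_id", "date", "bed_time", "rise_time"]
    for i in range(1, max_naps + 1):
        cols += [f"nap{i}_start", f"nap{i}_end"]
    rows = []
    for pid, days in diaries.items():
        for d in days:
            row: dict[str, object] = {
                "participant_id": pid,
                "date": d.bed_time.date().isoformat(),
                "bed_time": d.bed_time.strftime("%H:%M"),
                "rise_time": d.rise_time.strftime("%H:%M"),
            }
            for i, (a, b) in enumerate(d.naps, start=1):
                row[f"nap{i}_start"] = a.strftime("%H:%M")
                row[f"nap{i}_end"] = b.strftime("%H:%M")
            rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# covariates CSV


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the covariate table (participant_id, age, sex, sppb_total)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "age", "sex", "sppb_total"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"covariates CSV must have columns {sorted(required)}"
        )
    bad_sex = ~df["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise FormatError(f"unknown sex value {df['sex'][bad_sex].iloc[0]!r}")
    if ((df["sppb_total"] < 0) | (df["sppb_total"] > 12)).any():
        raise FormatError("sppb_total outside [0, 12]")
    return df[["participant_id", "age", "sex", "sppb_total"]].copy()


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df[["participant_id", "age", "sex", "sppb_total"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# device-format stub


def read_gt3x(path: str | Path) -> EpochSeries:
    """Not implemented: raw ActiGraph ingestion is out of scope.

    Device files (.gt3x / .agd) must be exported upstream — e.g. by ActiLife
    — to 60-s vector-magnitude counts and saved as the epoch CSV dialect
    ``participant_id,timestamp,vm_cpm`` that :func:`read_epochs` consumes.
    """
    raise NotImplementedError(
        "Raw .gt3x/.agd ingestion is not supported; export 60-s vector-"
        "magnitude epoch counts to the epoch CSV dialect and use read_epochs."
    )
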