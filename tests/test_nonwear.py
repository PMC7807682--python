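"""Non-wear detection against a brute-force oracle, and mask composition."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from actibed.epoch_io import DiaryDay
from actibed.nonwear import (
    NONWEAR,
    TIB,
    WEAR,
    NonwearParams,
    apply_masks,
    build_wear_mask,
    detect_nonwear,
)

from conftest import make_series


def oracle_detect(counts, min_duration=30, max_spikes=1, ceiling=100):
    """Independent reference: exhaustive left-to-right maximal-run search.

    A qualifying run starts and ends on a zero epoch, contains only zeros
    and sub-ceiling spikes (at most max_spikes of them), and is at least
    min_duration long.  Runs are chosen greedily: earliest start, maximal
    extent, never overlapping.
    """
    n = len(counts)
    out, cur = [], 0
    while True:
        best = None
        for i in range(cur, n):
            c = counts[i]
            if math.isnan(c) or c != 0:
                continue
            spikes, last_zero, j = 0, i, i
            while j < n:
                cj = counts[j]
                if math.isnan(cj) or cj >= ceiling:
                    break
                if cj == 0:
                    last_zero = j
                else:
                    spikes += 1
                    if spikes > max_spikes:
                        break
                j += 1
            end = last_zero + 1
            if end - i >= min_duration:
                best = (i, end)
                break
        if best is None:
            return out
        out.append(best)
        cur = best[1]


def random_series(rng, n):
    """Wear-like counts with inserted zero runs, spikes and breakers."""
    counts = rng.choice(
        [0.0, 50.0, 100.0, 150.0, 3000.0], size=n, p=[0.6, 0.12, 0.08, 0.08, 0.12]
    )
    # a few long zero runs so >=30-min windows actually occur
    for _ in range(rng.integers(0, 4)):
        i = int(rng.integers(0, n))
        counts[i : i + int(rng.integers(20, 90))] = 0.0
    return counts


class TestDetect:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            # 30 consecutive zeros flanked by wear -> one 30-epoch interval
            ([500] + [0] * 30 + [500], [(1, 31)]),
            # 29 zeros: below the minimum duration
            ([500] + [0] * 29 + [500], []),
            # one sub-100 spike inside 31 epochs of zeros counts as non-wear
            ([500] + [0] * 15 + [50] + [0] * 15 + [500], [(1, 32)]),
            # a 150-count epoch breaks the run
            ([500] + [0] * 15 + [150] + [0] * 15 + [500], []),
            # exactly 100 breaks the run (spike must be strictly below 100)
            ([500] + [0] * 15 + [100] + [0] * 15 + [500], []),
            # two spikes never fit in one run
            ([0] * 10 + [50] + [0] * 10 + [50] + [0] * 10, []),
            # runs truncated by the recording edge still qualify
            ([0] * 30 + [500], [(0, 30)]),
            ([500] + [0] * 30, [(1, 31)]),
        ],
    )
    def test_rule_examples(self, counts, expected):
        assert detect_nonwear(make_series(counts)) == expected

    def test_matches_oracle_on_random_series(self):
        rng = np.random.default_rng(2024)
        params = NonwearParams()
        for _ in range(300):
            counts = random_series(rng, int(rng.integers(10, 400)))
            got = detect_nonwear(make_series(counts), params)
            assert got == oracle_detect(list(counts))

    def test_matches_oracle_other_params(self):
        rng = np.random.default_rng(7)
        for max_spikes in (0, 2):
            params = NonwearParams(min_duration=20, max_spikes=max_spikes,
                                   spike_ceiling=60)
            for _ in range(100):
                counts = random_series(rng, int(rng.integers(10, 300)))
                got = detect_nonwear(make_series(counts), params)
                assert got == oracle_detect(
                    list(counts), min_duration=20, max_spikes=max_spikes, ceiling=60
                )

    def test_missing_epochs_break_runs(self):
        counts = [0.0] * 20 + [np.nan] + [0.0] * 20
        assert detect_nonwear(make_series(counts)) == []

    def test_lower_min_duration_only_adds_coverage(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            counts = random_series(rng, 300)
            s = make_series(counts)
            covered_30 = _coverage(detect_nonwear(s, NonwearParams(min_duration=30)), 300)
            covered_20 = _coverage(detect_nonwear(s, NonwearParams(min_duration=20)), 300)
            assert covered_30 <= covered_20  # set inclusion

    def test_spike_ceiling_irrelevant_without_affected_counts(self):
        # the ceiling only matters through counts in [old, new); without
        # them detection is identical.  (Raising the ceiling is NOT globally
        # monotone: a former run-breaker can become a spike, merge two runs
        # and exhaust the per-run spike budget earlier, shedding a tail.)
        rng = np.random.default_rng(6)
        for _ in range(60):
            counts = random_series(rng, 300)
            counts[(counts >= 100) & (counts < 200)] = 250.0
            s = make_series(counts)
            lo = detect_nonwear(s, NonwearParams(spike_ceiling=100))
            hi = detect_nonwear(s, NonwearParams(spike_ceiling=200))
            assert lo == hi

    def test_merged_run_via_raised_ceiling_can_shed_a_tail(self):
        # documented counterexample to naive ceiling monotonicity
        counts = [3000] + [0] * 30 + [150] + [0] * 30 + [50] + [0] * 5 + [3000]
        s = make_series(counts)
        lo = detect_nonwear(s, NonwearParams(spike_ceiling=100))
        hi = detect_nonwear(s, NonwearParams(spike_ceiling=200))
        assert lo == [(1, 31), (32, 68)]   # 150 breaks; 50 is an in-run spike
        assert hi == [(1, 62)]             # 150 merges, budget spent, tail lost


def _coverage(intervals, n):
    mask = np.zeros(n, bool)
    for i, j in intervals:
        mask[i:j] = True
    return frozenset(np.flatnonzero(mask).tolist())


class TestMasks:
    def test_tib_takes_precedence_over_nonwear(self):
        # all-zero night 22:30-06:30 is TIB, not NONWEAR
        counts = np.full(2 * 1440, 800.0)
        bed, rise = 22 * 60 + 30, 1440 + 6 * 60 + 30
        counts[bed:rise] = 0.0
        s = make_series(counts)
        diary = [DiaryDay(
            date=dt.date(2013, 5, 6),
            bed_time=pd.Timestamp("2013-05-06 22:30"),
            rise_time=pd.Timestamp("2013-05-07 06:30"),
        )]
        mask = apply_masks(s, detect_nonwear(s), diary)
        assert (mask.labels[bed:rise] == TIB).all()
        assert (mask.labels[:bed] == WEAR).all()

    def test_no_diary_no_zeros_all_wear(self):
        s = make_series(np.full(200, 700.0))
        mask = apply_masks(s, detect_nonwear(s), [])
        assert (mask.labels == WEAR).all()

    def test_daytime_zero_run_is_nonwear(self):
        counts = np.full(1440, 700.0)
        counts[14 * 60 : 14 * 60 + 40] = 0.0
        s = make_series(counts)
        mask = apply_masks(s, detect_nonwear(s), [])
        assert (mask.labels[14 * 60 : 14 * 60 + 40] == NONWEAR).all()
        assert (mask.labels == NONWEAR).sum() == 40

    def test_mask_conservation(self, small_cohort):
        for p in small_cohort[:5]:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mask = build_wear_mask(p.series, p.diary)
            c = mask.counts_by_label()
            assert c["WEAR"] + c["NONWEAR"] + c["TIB"] == len(p.series)

    def test_diary_outside_span_clipped_with_warning(self):
        s = make_series(np.full(1440, 700.0))
        diary = [DiaryDay(
            date=dt.date(2013, 5, 5),
            bed_time=pd.Timestamp("2013-05-05 22:00"),
            rise_time=pd.Timestamp("2013-05-06 07:00"),
        )]
        with pytest.warns(UserWarning, match="clipped"):
            mask = apply_masks(s, [], diary)
        assert (mask.labels[: 7 * 60] == TIB).all()
        assert (mask.labels[7 * 60 :] == WEAR).all()

    def test_out_of_bounds_interval_rejected(self):
        s = make_series(np.zeros(100))
        with pytest.raises(ValueError, match="bounds"):
            apply_masks(s, [(50, 200)], [])

    def test_sub_30min_still_period_next_to_sleep_stays_wear(self):
        # 20 min of lying still right after rise: merged detection would
        # call the whole night+morning non-wear; boundary-broken detection
        # leaves the 20 morning minutes as wear
        counts = np.full(2 * 1440, 900.0)
        bed, rise = 23 * 60, 1440 + 7 * 60
        counts[bed : rise + 20] = 0.0
        s = make_series(counts)
        diary = [DiaryDay(
            date=dt.date(2013, 5, 6),
            bed_time=pd.Timestamp("2013-05-06 23:00"),
            rise_time=pd.Timestamp("2013-05-07 07:00"),
        )]
        mask = build_wear_mask(s, diary)
        assert (mask.labels[rise : rise + 20] == WEAR).all()
        assert (mask.labels[bed:rise] == TIB).all()
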