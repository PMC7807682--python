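"""Intensity classification, daily/person summaries, validity, tertiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actibed.exposures import (
    ExclusionError,
    classify_intensity,
    daily_summaries,
    participant_exposure,
    tertile_assign,
)
from actibed.nonwear import NONWEAR, WEAR, WearMask

from conftest import make_series


def _mask(series, labels):
    return WearMask(series=series, labels=np.asarray(labels, np.int8))


def _one_day(counts_0500_on, fill=0.0):
    """A 1-day series whose epochs from 05:00 carry the given counts."""
    counts = np.full(1440, fill)
    counts[5 * 60 : 5 * 60 + len(counts_0500_on)] = counts_0500_on
    return make_series(counts)


class TestClassify:
    @pytest.mark.parametrize(
        "cpm, band",
        [(0, "SB"), (2302, "SB"), (2303, "MID"), (4999, "MID"), (5000, "HIGH")],
    )
    def test_cut_points(self, cpm, band):
        assert classify_intensity(cpm) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            classify_intensity(-1)


class TestDailySummary:
    def test_full_sb_day(self):
        s = _one_day([1000.0] * 600)
        labels = np.full(1440, NONWEAR)
        labels[5 * 60 : 5 * 60 + 600] = WEAR
        (day,) = daily_summaries(s, _mask(s, labels))
        assert day.wear_minutes == 600
        assert day.avg_cpm == 1000
        assert day.pct_sb == 100
        assert day.valid

    def test_band_split_arithmetic(self):
        s = _one_day([1000.0] * 300 + [3000.0] * 300)
        labels = np.full(1440, NONWEAR)
        labels[5 * 60 : 5 * 60 + 600] = WEAR
        (day,) = daily_summaries(s, _mask(s, labels))
        assert day.avg_cpm == 2000
        assert day.pct_sb == 50
        assert day.pct_mid == 50
        assert day.pct_sb + day.pct_mid + day.pct_high == pytest.approx(100, abs=1e-9)

    def test_nine_hours_wear_invalid(self):
        s = _one_day([1000.0] * 540)
        labels = np.full(1440, NONWEAR)
        labels[5 * 60 : 5 * 60 + 540] = WEAR
        (day,) = daily_summaries(s, _mask(s, labels))
        assert day.wear_minutes == 540
        assert not day.valid

    def test_epoch_before_window_excluded(self):
        s = make_series(np.full(1440, 0.0))
        counts = s.counts.copy()
        counts[4 * 60 + 30] = 9000.0   # 04:30, outside 05:00-24:00
        counts[12 * 60 : 12 * 60 + 600] = 1000.0
        s = make_series(counts)
        labels = np.full(1440, WEAR)
        (day,) = daily_summaries(s, _mask(s, labels))
        assert day.avg_cpm == pytest.approx(600_000 / day.wear_minutes)
        assert day.pct_high == 0  # the 04:30 epoch never contributes

    def test_zero_wear_day_flagged(self):
        s = make_series(np.zeros(1440))
        labels = np.full(1440, NONWEAR)
        (day,) = daily_summaries(s, _mask(s, labels))
        assert day.wear_minutes == 0
        assert not day.valid
        assert np.isnan(day.pct_sb)

    def test_avg_cpm_invariant_to_masked_counts(self):
        counts = np.full(1440, 1000.0)
        labels = np.full(1440, WEAR)
        labels[600:700] = NONWEAR
        a = daily_summaries(make_series(counts), _mask(make_series(counts), labels))
        counts2 = counts.copy()
        counts2[600:700] = 8888.0  # relabelled non-wear counts must not matter
        b = daily_summaries(make_series(counts2), _mask(make_series(counts2), labels))
        assert a[0].avg_cpm == b[0].avg_cpm
        assert a[0].pct_sb == b[0].pct_sb


def _summary(wear, pct_sb=100.0, avg=1000.0, valid=None, pct_mid=0.0, pct_high=0.0):
    from actibed.exposures import DailySummary
    import datetime as dt

    return DailySummary(
        date=dt.date(2013, 5, 6), wear_minutes=wear, avg_cpm=avg,
        pct_sb=pct_sb, pct_mid=pct_mid, pct_high=pct_high,
        valid=wear >= 600 if valid is None else valid,
    )


class TestParticipantExposure:
    def test_three_valid_days_excluded(self):
        days = [_summary(700)] * 3 + [_summary(500)] * 4
        with pytest.raises(ExclusionError, match="3 valid days"):
            participant_exposure(days, diary=[])

    @pytest.mark.parametrize("pct_sb, expected", [(66.0, True), (64.0, False)])
    def test_highly_sedentary_threshold(self, pct_sb, expected):
        days = [_summary(700, pct_sb=pct_sb, pct_mid=100 - pct_sb)] * 4
        exp = participant_exposure(days, diary=[])
        assert exp.highly_sedentary is expected

    def test_identical_days_pool_to_single_day_values(self):
        days = [_summary(700, pct_sb=60.0, avg=2000.0, pct_mid=40.0)] * 5
        exp = participant_exposure(days, diary=[])
        assert exp.avg_cpm == 2000
        assert exp.pct_sb == pytest.approx(60)
        assert exp.n_valid_days == 5

    def test_pooling_weights_by_wear_minutes(self):
        days = [
            _summary(600, pct_sb=100.0, avg=1000.0),
            _summary(1200, pct_sb=40.0, avg=4000.0, pct_mid=60.0),
        ] + [_summary(600, pct_sb=100.0, avg=1000.0)] * 2
        exp = participant_exposure(days, diary=[])
        # pooled: total counts / total wear, total SB minutes / total wear
        assert exp.avg_cpm == pytest.approx((1000 * 1800 + 4000 * 1200) / 3000)
        assert exp.pct_sb == pytest.approx((1800 + 0.4 * 1200) / 3000 * 100)
        mean = participant_exposure(days, diary=[], pooling="mean_of_days")
        assert mean.pct_sb == pytest.approx(np.mean([100, 40, 100, 100]))

    def test_band_percentages_sum_to_100(self, analysis_table):
        total = (
            analysis_table["pct_sb"]
            + analysis_table["pct_mid"]
            + analysis_table["pct_high"]
        )
        assert np.allclose(total, 100.0, atol=1e-9)


class TestTertiles:
    def test_one_to_nine(self):
        labels = tertile_assign(range(1, 10))
        assert labels == ["low"] * 3 + ["middle"] * 3 + ["high"] * 3

    def test_three_distinct_one_each(self):
        assert tertile_assign([10.0, 20.0, 30.0]) == ["low", "middle", "high"]

    def test_ties_go_to_lower_tertile(self):
        labels = tertile_assign([1, 1, 1, 2, 2, 2, 3, 3, 3])
        assert labels == ["low"] * 3 + ["middle"] * 3 + ["high"] * 3

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(0, 50), min_size=3, max_size=60).filter(
            lambda v: len(set(v)) > 1
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_stable(self, values, rnd):
        base = dict(zip(range(len(values)), tertile_assign(values)))
        idx = list(range(len(values)))
        rnd.shuffle(idx)
        shuffled = tertile_assign([values[i] for i in idx])
        assert all(shuffled[k] == base[i] for k, i in enumerate(idx))

    def test_degenerate_all_identical(self):
        with pytest.raises(ValueError, match="identical"):
            tertile_assign([5, 5, 5, 5])


def test_cohort_band_percentages_converge_to_mixture():
    """With a flat activity trait, pooled band occupancy ≈ mixture weights."""
    from actibed.pipeline import build_analysis_table
    from actibed.synthetic import CohortConfig, generate_cohort

    cohort = generate_cohort(
        CohortConfig(n_participants=20, seed=8, activity_trait_sd=0.0,
                     band_mixture=(0.5, 0.3, 0.2))
    )
    table, _ = build_analysis_table(cohort)
    assert abs(table["pct_sb"].mean() - 50) < 2
    assert abs(table["pct_mid"].mean() - 30) < 2
    assert abs(table["pct_high"].mean() - 20) < 2
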