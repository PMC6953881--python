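"""Construct-stage tests: classification, bouts, day summaries, sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actidays.constructs import (
    LPA,
    MVPA,
    NONWEAR,
    SEDENTARY,
    classify_epochs,
    days_to_frame,
    detect_mvpa_bouts,
    select_analytical_sample,
    summarize_day,
)
from actidays.errors import ConfigurationError, EmptySampleError, InputDataError
from conftest import make_epoch_series
from oracle_bouts import brute_force_bouts


class TestClassifyEpochs:
    def test_cutpoint_boundaries(self):
        ep = make_epoch_series([100.0, 50.0, 49.9, 100.1, 30.0])
        labels = classify_epochs(ep)
        # 100 mg belongs to LPA (MVPA is strictly above); 50 mg is LPA
        assert labels.tolist() == [LPA, LPA, SEDENTARY, MVPA, SEDENTARY]

    def test_nonwear_epochs_unlabeled(self):
        ep = make_epoch_series([120.0, 120.0], wear=[True, False])
        assert classify_epochs(ep).tolist() == [MVPA, NONWEAR]

    def test_threshold_order_enforced(self):
        ep = make_epoch_series([10.0])
        with pytest.raises(ConfigurationError):
            classify_epochs(ep, lpa_low=120, mvpa_threshold=100)


class TestDetectBouts:
    def test_ten_minutes_of_mvpa_is_one_bout(self):
        labels = np.full(130, SEDENTARY)
        labels[5:125] = MVPA  # 120 epochs at 5 s = 10 min
        bouts = detect_mvpa_bouts(labels, epoch_len=5)
        assert len(bouts) == 1
        b = bouts[0]
        assert (b.start_epoch, b.end_epoch) == (5, 125)
        assert b.duration_min == pytest.approx(10.0)
        assert b.fraction_above == 1.0

    def test_just_under_ten_minutes_is_no_bout(self):
        labels = np.full(130, SEDENTARY)
        labels[0:119] = MVPA  # 9 min 55 s
        assert detect_mvpa_bouts(labels, epoch_len=5) == []

    def test_nonwear_breaks_a_bout(self):
        labels = np.full(300, MVPA)
        labels[100] = NONWEAR
        bouts = detect_mvpa_bouts(labels, epoch_len=5)
        assert [(b.start_epoch, b.end_epoch) for b in bouts] == [(101, 300)]

    def test_interruption_run_bound(self):
        # a 25-epoch sedentary run (> 2 min at 5 s) must terminate the window
        labels = np.concatenate(
            [np.full(120, MVPA), np.full(25, SEDENTARY), np.full(120, MVPA)]
        )
        bouts = detect_mvpa_bouts(labels, epoch_len=5)
        assert [(b.start_epoch, b.end_epoch) for b in bouts] == [(0, 120), (145, 265)]

    def test_tolerated_interruption_extends_the_bout(self):
        labels = np.concatenate(
            [np.full(120, MVPA), np.full(20, SEDENTARY), np.full(120, MVPA)]
        )
        bouts = detect_mvpa_bouts(labels, epoch_len=5)
        assert [(b.start_epoch, b.end_epoch) for b in bouts] == [(0, 260)]
        assert bouts[0].fraction_above == pytest.approx(240 / 260)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        labels=st.lists(
            st.sampled_from([NONWEAR, SEDENTARY, LPA, MVPA]), min_size=1, max_size=120
        ),
        p=st.sampled_from([(2.0, 0.8), (1.0, 0.7), (3.0, 1.0)]),
    )
    def test_greedy_matches_brute_force_oracle(self, labels, p):
        min_bout, frac = p
        got = detect_mvpa_bouts(np.array(labels), 5.0, min_bout, frac)
        want = brute_force_bouts(labels, 5.0, min_bout, frac)
        assert [(b.start_epoch, b.end_epoch) for b in got] == want


class TestSummarizeDay:
    def _full_day(self, enmo_value=30.0, wear=None):
        return make_epoch_series(np.full(17280, enmo_value), wear=wear)

    def test_sedentary_day(self):
        ep = self._full_day(30.0)
        labels = classify_epochs(ep)
        days = summarize_day(ep, labels, [])
        assert len(days) == 1
        d = days[0]
        assert d.wear_hours == pytest.approx(24.0)
        assert d.overall_pa == pytest.approx(30.0)
        assert d.lpa_min == 0.0 and d.mvpa_bouted_min == 0.0
        assert d.valid and d.day_of_week == 1  # 2010-03-01 was a Monday

    def test_just_under_16h_wear_is_invalid(self):
        wear = np.zeros(17280, dtype=bool)
        wear[: int(15.9 * 720)] = True  # 15.9 h at 5-s epochs
        ep = self._full_day(30.0, wear=wear)
        d = summarize_day(ep, classify_epochs(ep), [])[0]
        assert d.wear_hours == pytest.approx(15.9, abs=0.01)
        assert not d.valid

    def test_zero_wear_day_has_nan_overall(self):
        ep = self._full_day(30.0, wear=np.zeros(17280, dtype=bool))
        d = summarize_day(ep, classify_epochs(ep), [])[0]
        assert np.isnan(d.overall_pa) and not d.valid

    def test_partial_days_excluded(self):
        ep = make_epoch_series(np.full(17280 + 100, 30.0))
        days = summarize_day(ep, classify_epochs(ep), [])
        assert len(days) == 1

    def test_bout_crossing_midnight_splits_minutes(self):
        enmo = np.full(2 * 17280, 30.0)
        enmo[17280 - 60 : 17280 + 60] = 150.0  # 5 min each side of midnight
        ep = make_epoch_series(enmo)
        labels = classify_epochs(ep)
        bouts = detect_mvpa_bouts(labels, epoch_len=5)
        days = summarize_day(ep, labels, bouts)
        assert [d.mvpa_bouted_min for d in days] == pytest.approx([5.0, 5.0])

    def test_minute_accounting_invariant(self, rng):
        enmo = rng.gamma(1.5, 40.0, size=17280)
        wear = rng.random(17280) > 0.1
        ep = self._full_day(0, wear=wear)
        ep.enmo[:] = enmo
        labels = classify_epochs(ep)
        n_wear = wear.sum()
        counted = sum((labels == c).sum() for c in (SEDENTARY, LPA, MVPA))
        assert counted == n_wear

    def test_raising_min_wear_hours_is_monotone(self, rng):
        frames = []
        for s in range(5):
            wear = rng.random(17280) > rng.uniform(0.1, 0.5)
            ep = self._full_day(30.0, wear=wear)
            labels = classify_epochs(ep)
            frames.append((ep, labels))
        prev = None
        for thresh in (8, 12, 16, 20):
            n_valid = sum(
                summarize_day(ep, labels, [], min_wear_hours=thresh)[0].valid
                for ep, labels in frames
            )
            if prev is not None:
                assert n_valid <= prev
            prev = n_valid


class TestSelectSample:
    def _days(self, sid, n_valid, n_total=7):
        rows = []
        for j in range(n_total):
            rows.append(
                {
                    "subject_id": sid,
                    "date": pd.Timestamp("2010-03-01") + pd.Timedelta(days=j),
                    "dow": j % 7 + 1,
                    "wear_hours": 20.0 if j < n_valid else 10.0,
                    "overall_pa_mg": 30.0 + j,
                    "lpa_min": 100.0,
                    "mvpa_bouted_min": 10.0,
                    "valid": j < n_valid,
                }
            )
        return rows

    def test_subject_below_minimum_excluded(self):
        df = pd.DataFrame(self._days("A", 5) + self._days("B", 7))
        sel = select_analytical_sample(df, min_valid_days=6, k_keep=6)
        assert sel.n_included == 1 and sel.excluded_ids == ["A"]
        m = sel.matrices["overall"]
        assert m.values.shape == (1, 6)
        # first six valid days retained chronologically
        assert m.values[0].tolist() == [30, 31, 32, 33, 34, 35]

    def test_balanced_cohort_keeps_everyone(self):
        df = pd.DataFrame(sum((self._days(f"S{i}", 6, 6) for i in range(10)), []))
        sel = select_analytical_sample(df)
        assert sel.n_included == 10 and sel.n_excluded == 0
        assert set(sel.matrices) == {"overall", "lpa", "mvpa"}
        assert sel.matrices["mvpa"].values.shape == (10, 6)

    def test_no_qualifying_subject_raises(self):
        df = pd.DataFrame(self._days("A", 3))
        with pytest.raises(EmptySampleError):
            select_analytical_sample(df)

    def test_schema_errors_are_explicit(self):
        with pytest.raises(InputDataError, match="missing columns"):
            select_analytical_sample(pd.DataFrame({"subject_id": ["A"]}))
        with pytest.raises(ConfigurationError):
            select_analytical_sample(pd.DataFrame(self._days("A", 6)), min_valid_days=1)


def test_days_to_frame_schema():
    ep = make_epoch_series(np.full(17280, 30.0))
    days = summarize_day(ep, classify_epochs(ep), [])
    df = days_to_frame(days)
    assert list(df.columns) == [
        "subject_id", "date", "dow", "wear_hours",
        "overall_pa_mg", "lpa_min", "mvpa_bouted_min", "valid",
    ]
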