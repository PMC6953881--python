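"""Reliability tests: one-way ICC, Spearman-Brown prophecy, minimum days."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from actidays.errors import InputDataError, ReliabilityDomainError
from actidays.reliability import (
    SpearmanBrownReliability,
    icc_single_day,
    min_days,
    reliability_report,
    round_half_away,
    spearman_brown,
)
from actidays.synthetic import CohortSimConfig, simulate_construct_matrix
from oracle_bouts import icc_oneway_definitional


class TestIccSingleDay:
    def test_identical_days_give_icc_one(self):
        m = np.repeat([[1.0], [2.0], [5.0]], 4, axis=1)
        icc, msb, msw = icc_single_day(m)
        assert icc == 1.0 and msw == 0.0

    def test_iid_noise_gives_icc_near_zero(self, rng):
        m = rng.normal(size=(2000, 4))
        icc, _, _ = icc_single_day(m)
        assert abs(icc) < 0.05

    def test_matches_definitional_sums_of_squares(self, rng):
        for _ in range(25):
            m = rng.normal(size=(5, 3)) + rng.normal(size=(5, 1))
            assert icc_single_day(m)[0] == pytest.approx(icc_oneway_definitional(m))

    def test_matches_pingouin_icc1(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        m = rng.normal(size=(12, 4)) + 2 * rng.normal(size=(12, 1))
        n, k = m.shape
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "day": np.tile(np.arange(k), n),
                "y": m.reshape(-1),
            }
        )
        tab = pg.intraclass_corr(long, targets="subject", raters="day", ratings="y")
        want = float(tab.loc[tab["Type"] == "ICC(1,1)", "ICC"].iloc[0])
        assert icc_single_day(m)[0] == pytest.approx(want, abs=1e-6)

    def test_negative_estimates_returned_as_is(self, rng):
        # force MSW > MSB: within-subject variation dominates
        m = np.array([[0.0, 10.0], [10.0, 0.0], [0.0, 10.0], [10.0, 0.0]])
        icc, _, _ = icc_single_day(m)
        assert icc < 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputDataError):
            icc_single_day(np.ones((4, 3)))
        with pytest.raises(InputDataError):
            icc_single_day(np.array([[1.0, 2.0]]))
        with pytest.raises(InputDataError):
            icc_single_day(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestSpearmanBrown:
    def test_printed_six_day_coefficients(self):
        assert spearman_brown(0.44, 6) == pytest.approx(0.825)
        assert round_half_away(spearman_brown(0.44, 6)) == 0.83
        assert round_half_away(spearman_brown(0.54, 6)) == 0.88

    def test_single_day_is_identity(self):
        for r in (0.1, 0.44, 0.99):
            assert spearman_brown(r, 1) == pytest.approx(r)

    def test_perfect_reliability_is_fixed_point(self):
        assert spearman_brown(1.0, 6) == 1.0

    def test_domain_errors(self):
        for bad in (0.0, -0.2):
            with pytest.raises(ReliabilityDomainError):
                spearman_brown(bad, 6)
        with pytest.raises(ReliabilityDomainError):
            spearman_brown(1.2, 6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        r=st.floats(0.01, 0.99),
        k=st.integers(1, 29),
        dr=st.floats(0.001, 0.3),
    )
    def test_strictly_increasing_in_both_arguments(self, r, k, dr):
        assert spearman_brown(r, k + 1) > spearman_brown(r, k)
        r2 = min(r + dr, 0.999)
        assert spearman_brown(r2, k) > spearman_brown(r, k) or r2 == r


class TestMinDays:
    def test_printed_minimum_days_for_overall_pa(self):
        assert min_days(0.44, 0.70) == 3  # children
        assert min_days(0.54, 0.70) == 2  # adults

    def test_boundary_strictness(self):
        assert min_days(0.70, 0.70, strict=True) == 2
        assert min_days(0.70, 0.70, strict=False) == 1

    def test_target_already_exceeded(self):
        assert min_days(0.9, 0.70) == 1

    def test_domain_errors(self):
        with pytest.raises(ReliabilityDomainError):
            min_days(0.0, 0.7)
        with pytest.raises(ReliabilityDomainError):
            min_days(0.5, 1.2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(r=st.floats(0.01, 0.99), t=st.floats(0.05, 0.95))
    def test_direct_evaluation_agrees_with_closed_form(self, r, t):
        """The returned k satisfies the strict target while k-1 does not —
        i.e. the closed-form inversion and direct curve evaluation agree."""
        k = min_days(r, t)
        assert spearman_brown(r, k) > t
        if k > 1:
            assert spearman_brown(r, k - 1) <= t

    def test_min_days_recovery_away_from_decision_boundaries(self):
        """Generic parameter recovery: at a true ICC of 0.5 (not adjacent to
        a min-days decision boundary at n=500) the estimated minimum days
        matches the truth in >= 95% of seeds."""
        md_true = min_days(0.5, 0.70)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            sim = simulate_construct_matrix(
                CohortSimConfig(n_subjects=500, n_days=6, sigma_between=1.0,
                                sigma_within=1.0, seed=seed)
            )
            icc_hat, _, _ = icc_single_day(sim.matrix)
            hits += min_days(icc_hat, 0.70) == md_true
        assert hits >= 95

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(r=st.floats(0.05, 0.95), k=st.integers(2, 15))
    def test_inverse_consistency_with_prophecy(self, r, k):
        rk = spearman_brown(r, k)
        gap = rk - spearman_brown(r, k - 1)
        target = rk - gap / 2
        if 0 < target < 1:
            assert min_days(r, target) == k


class TestEstimator:
    def test_fit_attributes_and_curve(self, rng):
        sim = simulate_construct_matrix(
            CohortSimConfig(n_subjects=300, n_days=6, sigma_between=1,
                            sigma_within=1.1, seed=1)
        )
        est = SpearmanBrownReliability(max_days=6).fit(sim.matrix)
        assert est.r_by_days_[1] == est.icc1_
        curve = [est.r_by_days_[k] for k in range(1, 7)]
        assert all(b > a for a, b in zip(curve, curve[1:]))
        assert est.min_days_ == min_days(est.icc1_, 0.70)
        assert est.predict([6])[0] == pytest.approx(spearman_brown(est.icc1_, 6))

    def test_sklearn_params_protocol(self):
        est = SpearmanBrownReliability(max_days=7, target=0.8)
        assert clone(est).get_params() == est.get_params()
        est.set_params(target=0.75)
        assert est.get_params()["target"] == 0.75

    def test_negative_icc_flagged_and_prophecy_refused(self):
        m = np.array([[0.0, 10.0], [10.0, 0.0], [0.0, 10.0], [10.0, 0.0]])
        est = SpearmanBrownReliability().fit(m)
        assert est.negative_icc_ and est.min_days_ is None
        with pytest.raises(ReliabilityDomainError):
            est.predict([3])


class TestReport:
    def test_three_constructs_three_results(self, rng):
        mats = {c: rng.normal(size=(30, 6)) + rng.normal(size=(30, 1))
                for c in ("overall", "lpa", "mvpa")}
        results = reliability_report(mats, K=6)
        assert len(results) == 3
        for r in results:
            assert set(r.r_by_days) == set(range(1, 7))
            rec = r.to_record()
            assert rec["icc1_2dp"] == round_half_away(r.icc1)

    def test_perfect_icc_gives_flat_curve(self):
        m = np.repeat([[1.0], [4.0], [9.0]], 6, axis=1)
        (res,) = reliability_report({"overall": m}, K=6)
        assert all(v == 1.0 for v in res.r_by_days.values())
        assert res.min_days == 1

    def test_curve_endpoints_for_target_icc(self):
        """A cohort tuned to ICC 0.44 yields the (0.44, 0.825) endpoints."""
        sigma_b = 1.0
        sigma_w = sigma_b * np.sqrt((1 - 0.44) / 0.44)
        sim = simulate_construct_matrix(
            CohortSimConfig(n_subjects=4000, n_days=6, sigma_between=sigma_b,
                            sigma_within=sigma_w, seed=2)
        )
        assert sim.icc_true == pytest.approx(0.44)
        est = SpearmanBrownReliability().fit(sim.matrix)
        assert est.r_by_days_[1] == pytest.approx(0.44, abs=0.03)
        assert est.r_by_days_[6] == pytest.approx(0.825, abs=0.03)


def test_round_half_away_ties_go_away_from_zero():
    assert round_half_away(0.825) == 0.83
    assert round_half_away(-0.825) == -0.83
    assert round_half_away(0.8757) == 0.88
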