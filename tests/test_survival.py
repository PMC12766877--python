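"""Lesion/patient classification, Kaplan-Meier, Cox solver, threshold sweep."""

import math

import numpy as np
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
import pandas as pd

from fesmeta.evidence import LesionRecord, PatientRecord
from fesmeta.survival import (
    HeterogeneityClass,
    classify_lesion,
    classify_patient,
    cox_binary,
    cox_loglik_score_info,
    km_curve,
    threshold_grid,
    threshold_sweep,
)


def _patient(pid, suvs, pfs=10.0, event=True):
    return PatientRecord(
        pid, tuple(LesionRecord(pid, s) for s in suvs), pfs, event
    )


def naive_efron_loglik(times, events, group, beta):
    """Independent oracle: explicit Efron partial log-likelihood, plain loops."""
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    x = np.asarray(group, int)
    ll = 0.0
    for tau in np.unique(t[e]):
        risk = [i for i in range(len(t)) if t[i] >= tau]
        tied = [i for i in range(len(t)) if e[i] and t[i] == tau]
        d = len(tied)
        s0 = sum(math.exp(beta * x[i]) for i in risk)
        s0h = sum(math.exp(beta * x[i]) for i in tied)
        ll += beta * sum(x[i] for i in tied)
        for l in range(d):
            ll -= math.log(s0 - (l / d) * s0h)
    return ll


class TestClassification:
    @pytest.mark.parametrize(
        "suv, thr, positive",
        [(1.8, 1.8, True), (1.79, 1.8, False), (6.0, 1.8, True), (0.0, 1.8, False)],
    )
    def test_lesion_boundary_inclusive(self, suv, thr, positive):
        assert classify_lesion(suv, thr) is positive

    @pytest.mark.parametrize(
        "suvs, expected",
        [
            ([2.5, 3.1], HeterogeneityClass.all_positive),
            ([2.5, 1.2], HeterogeneityClass.heterogeneous),
            ([1.0, 1.5], HeterogeneityClass.all_negative),
        ],
    )
    def test_patient_classes(self, suvs, expected):
        cls = classify_patient(_patient("p", suvs), 1.8)
        assert cls.label is expected
        assert (cls.label is HeterogeneityClass.all_positive) == (
            cls.n_negative_lesions == 0
        )
        assert (cls.label is HeterogeneityClass.all_negative) == (
            cls.n_negative_lesions == cls.n_lesions
        )


class TestKaplanMeier:
    def test_uncensored_odd_n_median(self):
        curve = km_curve([1, 2, 3, 4, 5], [True] * 5)
        assert curve.median_months == 3.0

    def test_hand_product_limit_with_censoring(self):
        # events at 1 and 3, censored at 2: S(1) = 2/3, S(3) = 0
        curve = km_curve([1, 2, 3], [True, False, True])
        assert curve.event_times == (1.0, 3.0)
        assert curve.survival[0] == pytest.approx(2 / 3, rel=1e-12)
        assert curve.survival[1] == pytest.approx(0.0, abs=1e-12)
        assert curve.median_months == 3.0
        assert curve.at_risk == (3, 1)

    def test_all_censored_is_flat_with_undefined_median(self):
        curve = km_curve([4, 6, 9], [False] * 3)
        assert curve.event_times == ()
        assert curve.median_months is None

    def test_reproduces_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(8.0, 40).round(1) + 0.1
        curve = km_curve(t, [True] * 40)
        for tt, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx((t > tt).mean(), abs=1e-12)

    def test_median_ci_upper_can_be_unbounded(self):
        # heavy censoring late: the confidence band never recrosses 0.5
        t = [1, 2, 3, 10, 11, 12, 13, 14]
        e = [True, True, True, False, False, False, False, False]
        curve = km_curve(t, e)
        assert math.isinf(curve.median_ci[1])


class TestCoxBinary:
    def test_identical_groups_give_unit_hr(self):
        t = [2, 4, 6, 8, 3, 5] * 2
        e = [True, True, False, True, True, False] * 2
        g = [False] * 6 + [True] * 6
        fit = cox_binary(t, e, g)
        assert fit.hr == pytest.approx(1.0, abs=1e-9)
        assert fit.converged

    def test_matches_brute_force_grid_oracle_small_n(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(10, 12).round(0) + 1.0
        x = np.array([0, 1] * 6)
        e = np.ones(12, bool)
        fit = cox_binary(t, e, x.astype(bool))
        grid = np.arange(-5, 5.00005, 1e-4)
        lls = [naive_efron_loglik(t, e, x, b) for b in grid[::100]]
        coarse = grid[::100][int(np.argmax(lls))]
        fine = np.arange(coarse - 0.02, coarse + 0.02, 1e-4)
        best = fine[int(np.argmax([naive_efron_loglik(t, e, x, b) for b in fine]))]
        assert abs(fit.log_hr - best) < 1e-4

    def test_matches_lifelines(self):
        rng = np.random.default_rng(21)
        n = 80
        x = rng.integers(0, 2, n)
        t = rng.exponential(10.0 / np.exp(0.7 * x)).round(1) + 0.1
        e = rng.random(n) < 0.75
        fit = cox_binary(t, e, x.astype(bool))
        df = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
        ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.log_hr == pytest.approx(ref.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(ref.standard_errors_["x"], rel=1e-4)

    def test_rank_invariance_under_time_scaling(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        e = [True, True, False, True, True, True]
        g = [False, True, False, True, True, False]
        a = cox_binary(t, e, g)
        b = cox_binary([2 * x for x in t], e, g)
        assert b.log_hr == pytest.approx(a.log_hr, abs=1e-12)
        assert b.se == pytest.approx(a.se, rel=1e-12)

    def test_score_at_zero_equals_logrank(self):
        rng = np.random.default_rng(8)
        n = 30
        x = rng.integers(0, 2, n)
        t = rng.exponential(10.0 / np.exp(0.5 * x), n)  # continuous: no ties
        e = rng.random(n) < 0.8
        _, score, info = cox_loglik_score_info(0.0, t, e, x.astype(bool))
        ref = logrank_test(t[x == 1], t[x == 0], e[x == 1], e[x == 0])
        assert score**2 / info == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_separated_groups_flag_monotone_likelihood(self):
        t = [1, 2, 3, 10, 11, 12]
        e = [True] * 6
        g = [True, True, True, False, False, False]  # all early events in group 1
        fit = cox_binary(t, e, g)
        assert fit.monotone and not fit.converged
        assert math.isinf(fit.ci_high)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cox_binary([1, 2], [True, True], [True, True])
        with pytest.raises(ValueError):
            cox_binary([1, 2], [False, False], [True, False])


class TestThresholdSweep:
    def test_primary_grid_has_23_points(self):
        grid = threshold_grid(1.8, 4.0, 0.1)
        assert len(grid) == 23
        assert grid[0] == 1.8 and grid[-1] == 4.0

    def test_all_positive_group_never_grows(self, small_cohort):
        res = threshold_sweep(small_cohort, 1.8, 4.0, 0.1)
        sizes = [r.n_all_positive for r in res.rows]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_group_sizes_partition_cohort(self, small_cohort):
        res = threshold_sweep(small_cohort, 1.8, 4.0, 0.1)
        assert all(
            r.n_all_positive + r.n_other == len(small_cohort) for r in res.rows
        )

    def test_threshold_below_all_lesions_is_degenerate(self):
        patients = [_patient(f"p{i}", [5.0, 6.0], pfs=i + 1.0) for i in range(6)]
        res = threshold_sweep(patients, 0.5, 0.5, 0.1)
        (row,) = res.rows
        assert row.n_all_positive == 6 and row.cox is None
        assert row.cox_reason is not None

    def test_frame_columns(self, small_cohort):
        df = threshold_sweep(small_cohort, 1.8, 2.0, 0.1).to_frame()
        assert list(df.columns) == [
            "threshold", "n_all_pos", "n_other", "hr", "hr_lo", "hr_hi",
            "median_all_pos", "median_other",
        ]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([], 1.8, 4.0, 0.1)
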