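"""Optimal-level selection, additive prediction, CI, quality loss, linearity."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from lfa_taguchi import (
    ResponseTable,
    calibration_report,
    compare_confirmation,
    confirmation_ci,
    equivalent_sample_size,
    predict_snr,
    quality_loss_ratio,
    select_optimal,
)
from tests.conftest import (
    REFERENCE_INPUT_LEVELS,
    REFERENCE_OPTIMAL_MEASURED,
    REFERENCE_ORIGINAL_MEASURED,
)


class TestSelectOptimal:
    def test_reference_table_selection(self, reference_level_means):
        table = ResponseTable.from_level_means(reference_level_means)
        assert select_optimal(table) == {"A": 2, "B": 2, "C": 1, "D": 1}

    def test_all_equal_ties_to_level_one(self):
        table = ResponseTable.from_level_means(
            {f: (-5.0, -5.0, -5.0) for f in "ABCD"}
        )
        assert select_optimal(table) == {f: 1 for f in "ABCD"}

    def test_increasing_factor_picks_level_three(self):
        means = {f: (-5.0, -5.0, -5.0) for f in "ABCD"}
        means["C"] = (-7.0, -6.0, -5.0)
        table = ResponseTable.from_level_means(means)
        assert select_optimal(table)["C"] == 3


class TestPredictSnr:
    def test_reference_two_factor_prediction(self, reference_level_means):
        table = ResponseTable.from_level_means(reference_level_means)
        pred = predict_snr(table, {"A": 2, "B": 2}, ("A", "B"))
        assert pred == pytest.approx(-9.35, abs=0.05)

    def test_single_factor_prediction(self, reference_level_means):
        table = ResponseTable.from_level_means(reference_level_means)
        pred = predict_snr(table, {"B": 2}, ("B",))
        assert pred == pytest.approx(table.grand_mean + 2.33, abs=0.05)
        assert pred == pytest.approx(-11.0, abs=0.05)

    def test_flat_table_predicts_grand_mean(self):
        table = ResponseTable.from_level_means(
            {f: (-5.0, -5.0, -5.0) for f in "ABCD"}
        )
        levels = {f: 2 for f in "ABCD"}
        assert predict_snr(table, levels, tuple("ABCD")) == pytest.approx(-5.0)

    def test_empty_subset_rejected(self, reference_level_means):
        table = ResponseTable.from_level_means(reference_level_means)
        with pytest.raises(ValueError):
            predict_snr(table, {"A": 2}, ())


class TestEquivalentSampleSize:
    def test_two_factors_of_two_dof(self):
        assert equivalent_sample_size(9, [2, 2]) == pytest.approx(9 / 5)

    def test_no_included_factors(self):
        assert equivalent_sample_size(9, []) == 9.0

    def test_one_factor(self):
        assert equivalent_sample_size(9, [2]) == 3.0


class TestConfirmationCI:
    def test_reference_interval(self):
        # 99% two-sided CI with the published pooled error
        ci = confirmation_ci(mse=1.33, fe=4, me=9 / 5, mr=3, alpha=0.01)
        assert ci == pytest.approx(5.01, abs=0.01)

    def test_zero_mse_zero_width(self):
        assert confirmation_ci(0.0, 4, 1.8, 3, 0.01) == 0.0

    def test_infinite_replication_limit(self):
        from scipy import stats as sps

        ci = confirmation_ci(2.0, 4, 1.0, 10**9, 0.05)
        t = sps.t.ppf(0.975, 4)
        assert ci == pytest.approx(t * math.sqrt(2.0), rel=1e-4)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            confirmation_ci(1.0, 4, 1.8, 3, alpha=1.5)


class TestQualityLossRatio:
    def test_three_db_gain_halves_loss(self):
        assert quality_loss_ratio(-7.0, -10.0) == pytest.approx(0.5)

    def test_no_gain_no_change(self):
        assert quality_loss_ratio(-10.0, -10.0) == 1.0

    def test_reference_gain_formula_value(self):
        # half-per-3-dB rule on a 1.98 dB gain: 0.5^(1.98/3) = 0.633
        ratio = quality_loss_ratio(-10.91, -12.89)
        assert ratio == pytest.approx(0.633, abs=0.0005)

    @given(st.floats(-20, 0), st.floats(-20, 0))
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_gain(self, a, b):
        assume(abs(a - b) > 1e-9)
        lo, hi = sorted((a, b))
        assert quality_loss_ratio(hi, -10.0) < quality_loss_ratio(lo, -10.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            quality_loss_ratio(math.inf, -10.0)


class TestCalibrationReport:
    def test_perfect_line(self):
        x = np.arange(10.0)
        rep = calibration_report(x, x)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.sd_of_residuals == pytest.approx(0.0, abs=1e-12)
        assert rep.cv_percent == pytest.approx(0.0, abs=1e-12)

    def test_reference_original_linearity(self):
        rep = calibration_report(REFERENCE_INPUT_LEVELS, REFERENCE_ORIGINAL_MEASURED)
        # frozen from textbook OLS on the published 11-point series
        assert rep.r_squared == pytest.approx(0.99780, abs=5e-4)

    def test_optimal_more_linear_than_original(self):
        r_orig = calibration_report(
            REFERENCE_INPUT_LEVELS, REFERENCE_ORIGINAL_MEASURED
        )
        r_opt = calibration_report(
            REFERENCE_INPUT_LEVELS, REFERENCE_OPTIMAL_MEASURED
        )
        assert r_opt.r_squared > r_orig.r_squared
        assert r_opt.sd_of_residuals < r_orig.sd_of_residuals
        assert r_opt.cv_percent < r_orig.cv_percent

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            calibration_report([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareConfirmation:
    def test_reference_verdict(self):
        res = compare_confirmation(-9.35, -10.91, 5.01)
        assert res.deviation == pytest.approx(1.56, abs=1e-9)
        assert res.within_ci

    def test_exact_agreement(self):
        res = compare_confirmation(-10.0, -10.0, 1.0)
        assert res.deviation == 0.0 and res.within_ci

    def test_outside_interval(self):
        assert not compare_confirmation(-5.0, -12.0, 3.0).within_ci
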