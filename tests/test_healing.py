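"""Contraction statistic, predictor rules and method comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import woundplanim as wp
from woundplanim.errors import (
    IncompleteDataError,
    InsufficientSeriesError,
    InvalidBaselineError,
    InvalidParameterError,
    UndefinedCorrelationError,
)

# printed per-wound percentage-error columns of the published agreement table
TABLE2 = {
    "digimizer": [1.44, 2.63, 1.88, 3.76, 0.99, 0.94, 3.00, -6.60],
    "matlab": [-2.60, 5.41, 0.99, -0.80, -2.75, -0.73, -0.31, -6.06],
    "caliper_kundin": [-1.78, -24.01, -62.72, -195.16, -32.15, -35.12, -16.71, 8.54],
    "ruler_kundin": [-16.07, -25.66, -38.86, -195.16, -32.98, 0.45, -30.90, -18.44],
}


class TestContraction:
    def test_no_change_is_zero(self):
        assert wp.contraction_percentage(10.0, 10.0) == 0.0

    def test_quarter_reduction(self):
        assert wp.contraction_percentage(10.0, 7.5) == pytest.approx(25.0)

    def test_growth_is_negative(self):
        assert wp.contraction_percentage(8.0, 10.0) == pytest.approx(-25.0)

    def test_full_healing_is_hundred(self):
        assert wp.contraction_percentage(5.0, 0.0) == pytest.approx(100.0)

    def test_invalid_baseline(self):
        with pytest.raises(InvalidBaselineError):
            wp.contraction_percentage(0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        s0=st.floats(0.1, 500.0),
        s1=st.floats(0.0, 500.0),
        s2=st.floats(0.0, 500.0),
    )
    def test_strictly_decreasing_in_current_area(self, s0, s1, s2):
        lo, hi = sorted([s1, s2])
        if (hi - lo) / s0 < 1e-9:  # below float resolution of the statistic
            return
        assert wp.contraction_percentage(s0, lo) > wp.contraction_percentage(s0, hi)


class TestBuildSeries:
    def test_basic_arithmetic(self):
        s = wp.build_series([10.0, 9.0, 8.0])
        assert s.coi == pytest.approx((0.0, 10.0, 20.0))
        assert s.normalized == pytest.approx((1.0, 0.9, 0.8))

    def test_constant_series(self):
        s = wp.build_series([4.0, 4.0, 4.0])
        assert all(c == 0.0 for c in s.coi)

    def test_non_monotone_allowed(self):
        s = wp.build_series([10.0, 12.0, 9.0])
        assert s.coi == pytest.approx((0.0, -20.0, 10.0))

    def test_too_short(self):
        with pytest.raises(InsufficientSeriesError):
            wp.build_series([10.0])

    def test_weeks_must_increase_from_zero(self):
        with pytest.raises(InvalidParameterError):
            wp.build_series([10.0, 9.0], weeks=[1, 2])
        with pytest.raises(InvalidParameterError):
            wp.build_series([10.0, 9.0, 8.0], weeks=[0, 2, 2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        areas=st.lists(st.floats(0.01, 300.0), min_size=2, max_size=8)
    )
    def test_normalized_coi_identity(self, areas):
        s = wp.build_series(areas)
        for n, c in zip(s.normalized, s.coi):
            assert n == pytest.approx(1.0 - c / 100.0)


class TestClassifyHealing:
    def test_two_week_boundary_inclusive(self):
        s = wp.build_series([100.0, 90.0, 75.0])  # 25% at week 2 exactly
        verdict, _ = wp.classify_healing(s, "two_week_25")
        assert verdict == "predicted_to_heal"

    def test_two_week_below_threshold(self):
        s = wp.build_series([100.0, 95.0, 80.0])  # 20% at week 2
        verdict, _ = wp.classify_healing(s, "two_week_25")
        assert verdict == "reassess"

    def test_four_week_forty_not_met(self):
        s = wp.build_series([100.0, 90.0, 80.0, 70.0, 65.0])  # 35% at week 4
        verdict, why = wp.classify_healing(s, "four_week_40")
        assert verdict == "reassess"
        assert "40" in why

    def test_four_week_boundary(self):
        s = wp.build_series([100.0, 90.0, 80.0, 70.0, 60.0])  # exactly 40%
        verdict, _ = wp.classify_healing(s, "four_week_40")
        assert verdict == "predicted_to_heal"

    def test_flat_series_reassess_under_every_rule(self):
        s = wp.build_series([50.0] * 5)  # weeks 0-4, no contraction
        for rule in wp.healing.RULES:
            verdict, _ = wp.classify_healing(s, rule)
            assert verdict == "reassess", rule

    def test_weekly_rule_uses_mean_weekly_rate(self):
        s = wp.build_series([100.0, 90.0, 81.0])  # 10%/week compounding
        assert wp.classify_healing(s, "weekly_10_15")[0] == "predicted_to_heal"
        slow = wp.build_series([100.0, 95.0, 90.25])  # 5%/week
        assert wp.classify_healing(slow, "weekly_10_15")[0] == "reassess"

    def test_window_rule_met_early(self):
        s = wp.build_series([100.0, 85.0, 78.0])  # 22% at week 2
        assert (
            wp.classify_healing(s, "two_to_four_week_20_40")[0]
            == "predicted_to_heal"
        )

    def test_window_rule_open_window_indeterminate(self):
        s = wp.build_series([100.0, 95.0, 85.0, 82.0])  # 18% by week 3
        assert wp.classify_healing(s, "two_to_four_week_20_40")[0] == "indeterminate"

    def test_window_rule_closed_window_reassess(self):
        s = wp.build_series([100.0, 95.0, 90.0, 88.0, 85.0])  # 15% by week 4
        assert wp.classify_healing(s, "two_to_four_week_20_40")[0] == "reassess"

    def test_insufficient_series_names_horizon(self):
        s = wp.build_series([100.0, 90.0])
        with pytest.raises(InsufficientSeriesError, match="week-2"):
            wp.classify_healing(s, "two_week_25")
        with pytest.raises(InsufficientSeriesError, match="week-4"):
            wp.classify_healing(s, "four_week_40")

    def test_unknown_rule(self):
        s = wp.build_series([10.0, 9.0, 8.0])
        with pytest.raises(InvalidParameterError):
            wp.classify_healing(s, "six_week_60")


class TestPercentDifference:
    @pytest.mark.parametrize(
        "value,expected",
        [(37.5, 52.63), (24.80, 0.94), (24.34, -0.94), (32.67, 32.97), (25.24, 2.73)],
    )
    def test_published_rows_vs_reference(self, value, expected):
        assert round(wp.percent_difference(value, 24.57), 2) == expected

    def test_self_difference_zero(self):
        assert wp.percent_difference(3.7, 3.7) == 0.0

    def test_invalid_reference(self):
        with pytest.raises(wp.healing.InvalidReferenceError):
            wp.percent_difference(1.0, 0.0)


class TestMeanError:
    def test_published_mean_row(self):
        means = {k: round(wp.mean_error(v), 2) for k, v in TABLE2.items()}
        assert means == {
            "digimizer": 1.01,
            "matlab": -0.86,
            "caliper_kundin": -44.89,
            "ruler_kundin": -44.70,
        }

    def test_signed_cancellation(self):
        assert wp.mean_error([5.0, -5.0]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            wp.mean_error([])


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert wp.pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert wp.pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(9)
        x, y = rng.random(20), rng.random(20)
        cx, cy = x - x.mean(), y - y.mean()
        expected = np.sum(cx * cy) / np.sqrt(np.sum(cx**2) * np.sum(cy**2))
        assert wp.pearson_r(x, y) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            wp.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
        seed=st.integers(0, 50),
    )
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(10), rng.random(10)
        assert wp.pearson_r(a * x + b, y) == pytest.approx(
            wp.pearson_r(x, y), abs=1e-9
        )


class TestCompareMethods:
    def test_reference_alone_all_zero(self):
        report = wp.compare_methods(
            {"w1": {"pixel": 10.0}, "w2": {"pixel": 5.0}}, "pixel"
        )
        assert (report.per_wound_errors["pixel"] == 0).all()

    def test_single_wound_published_rows(self):
        areas = {
            "fig_wound": {
                "klonk": 24.57,
                "manual": 24.80,
                "digimizer": 24.34,
                "matlab": 25.24,
                "caliper_kundin": 32.67,
                "ruler": 37.5,
            }
        }
        report = wp.compare_methods(areas, "klonk")
        err = report.per_wound_errors.loc["fig_wound"]
        assert round(err["ruler"], 2) == 52.63
        assert round(err["manual"], 2) == 0.94
        assert round(err["caliper_kundin"], 2) == 32.97

    def test_mean_errors_are_column_means(self):
        rng = np.random.default_rng(4)
        wounds = {
            f"w{i}": {"ref": a, "other": a * rng.uniform(0.8, 1.2)}
            for i, a in enumerate(rng.uniform(2, 50, 6))
        }
        report = wp.compare_methods(wounds, "ref")
        pd.testing.assert_series_equal(
            report.mean_errors, report.per_wound_errors.mean()
        )
        assert report.mean_errors["other"] == pytest.approx(
            wp.mean_error(report.per_wound_errors["other"].tolist())
        )

    def test_correlations_near_one_for_agreeing_methods(self):
        rng = np.random.default_rng(5)
        truth = rng.uniform(5, 60, 8)
        wounds = {
            f"w{i}": {
                "ref": t,
                "m1": t * (1 + rng.normal(0, 0.01)),
                "m2": t * (1 + rng.normal(0, 0.02)),
            }
            for i, t in enumerate(truth)
        }
        report = wp.compare_methods(wounds, "ref")
        assert report.correlations.loc["ref", "m1"] > 0.99
        assert report.correlations.loc["ref", "m2"] > 0.99

    def test_missing_reference_raises(self):
        with pytest.raises(IncompleteDataError, match="w2"):
            wp.compare_methods(
                {"w1": {"ref": 1.0}, "w2": {"other": 2.0}}, "ref"
            )

    def test_csv_roundtrip(self, tmp_path):
        report = wp.compare_methods(
            {"w1": {"ref": 10.0, "m": 11.0}, "w2": {"ref": 5.0, "m": 4.5}}, "ref"
        )
        out = tmp_path / "table.csv"
        report.to_csv(out)
        df = pd.read_csv(out)
        assert set(df.columns) == {
            "wound_id", "method", "area_cm2", "pct_diff_vs_reference"
        }
        assert len(df) == 4
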