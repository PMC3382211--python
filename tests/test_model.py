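"""Learning-curve model: evaluation, fitting, derived summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvltcurve import (
    DegenerateComparisonError,
    InputError,
    ModelFit,
    ModelParams,
    ParameterError,
    RecallSeries,
    compare_coefficients,
    evaluate_model,
    fit_learning_curve,
    learning_slope,
    max_minus_first,
)
from cvltcurve.reference_data import GROUP_TRIAL_MEANS, PUBLISHED_CURVE_FITS

X5 = np.arange(1, 6, dtype=float)


def _series(counts):
    return RecallSeries.from_counts(counts)


def _make_fit(b2, b3, b4, se):
    """Hand-built ModelFit for coefficient-comparison tests."""
    return ModelFit(
        params=ModelParams(b2, b3, b4),
        se={"B2": se[0], "B3": se[1], "B4": se[2]},
        r_squared=1.0,
        residuals=np.zeros(5),
        converged=True,
        n_points=5,
    )


class TestEvaluate:
    def test_trial_one_returns_b3_exactly(self):
        p = ModelParams(0.65, 7.28, 14.17)
        assert evaluate_model(p, 1) == p.b3

    def test_closed_form_value(self):
        p = ModelParams(0.65, 7.28, 14.17)
        expected = 14.17 - (14.17 - 7.28) * np.exp(-1.3)
        assert evaluate_model(p, 3) == pytest.approx(expected)
        assert evaluate_model(p, 3) == pytest.approx(12.29, abs=0.005)

    def test_flat_curve_when_b3_equals_b4(self):
        p = ModelParams(1.3, 9.5, 9.5)
        x = np.linspace(1, 20, 7)
        assert np.allclose(evaluate_model(p, x), 9.5)

    def test_invalid_learning_rate_rejected(self):
        with pytest.raises(ParameterError):
            ModelParams(0.0, 7.0, 14.0)
        with pytest.raises(ParameterError):
            ModelParams(-0.5, 7.0, 14.0)

    def test_trial_below_one_rejected(self):
        with pytest.raises(InputError):
            evaluate_model(ModelParams(0.5, 6, 12), 0.5)

    @settings(deadline=None, derandomize=True)
    @given(
        b2=st.floats(0.05, 2.0),
        b3=st.floats(0.0, 10.0),
        gap=st.floats(0.5, 10.0),
        x=st.floats(1.0, 10.0),  # past ~10 time constants the curve is flat
    )
    def test_increasing_toward_asymptote(self, b2, b3, gap, x):
        """Curve rises strictly when B4 > B3 and approaches B4."""
        p = ModelParams(b2, b3, b3 + gap)
        y1, y2 = evaluate_model(p, x), evaluate_model(p, x + 0.5)
        assert y2 > y1
        assert abs(evaluate_model(p, 1e6) - p.b4) < 1e-9

    def test_decreasing_when_b4_below_b3(self):
        p = ModelParams(0.8, 12.0, 8.0)
        y = evaluate_model(p, np.arange(1, 8, dtype=float))
        assert np.all(np.diff(y) < 0)


class TestRecallSeries:
    def test_counts_out_of_range_rejected(self):
        with pytest.raises(InputError):
            _series([5, 8, 17, 9, 11])

    def test_non_increasing_trials_rejected(self):
        with pytest.raises(InputError):
            RecallSeries(np.array([1, 2, 2]), np.array([3, 4, 5]))

    def test_configurable_bound_for_other_lists(self):
        s = RecallSeries.from_counts([3, 5, 7, 8, 9], max_score=9)
        assert len(s) == 5


class TestFit:
    def test_noiseless_recovery_exact(self, noiseless_series):
        params, series = noiseless_series
        fit = fit_learning_curve(series)
        assert fit.converged
        assert np.allclose(fit.params.as_tuple(), params.as_tuple(), atol=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "group",
        ["healthy_all", "ms_all", "healthy_male", "ms_male_lower"],
    )
    def test_reproduces_published_group_fits(self, group):
        """Refitting published averaged curves recovers published coefficients."""
        fit = fit_learning_curve(_series(GROUP_TRIAL_MEANS[group]))
        pub = PUBLISHED_CURVE_FITS[group]
        for name in ("B2", "B3", "B4"):
            if pub[name] is not None:
                assert fit.params[name] == pytest.approx(pub[name], abs=0.05)
        if pub["r_squared"] is not None:
            assert fit.r_squared == pytest.approx(pub["r_squared"], abs=0.001)

    def test_too_few_trials_rejected(self):
        with pytest.raises(InputError):
            fit_learning_curve(RecallSeries.from_counts([5, 9]))

    def test_initialization_invariance(self):
        """Well-conditioned data: the optimum is independent of the start."""
        truth = ModelParams(0.8, 5.0, 12.0)
        rng = np.random.default_rng(7)
        y = np.clip(evaluate_model(truth, X5) + rng.normal(0, 0.5, 5), 0, 16)
        series = RecallSeries(X5, y)
        fits = [
            fit_learning_curve(series, init=ModelParams(b2, b3, b4))
            for b2, b3, b4 in [(0.2, 4.0, 10.0), (0.5, 6.0, 13.0), (2.0, 5.0, 15.0)]
        ]
        ref = np.array(fits[0].params.as_tuple())
        for f in fits[1:]:
            assert np.allclose(np.array(f.params.as_tuple()), ref, atol=1e-8)

    def test_residuals_and_r_squared_definition(self, healthy_all_series):
        fit = fit_learning_curve(healthy_all_series)
        y = healthy_all_series.counts
        ss_res = float(np.sum(fit.residuals**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
        assert len(fit.residuals) == fit.n_points == 5

    def test_asymptotic_se_matches_numerical_jacobian(self, healthy_all_series):
        """SEs agree with a brute-force finite-difference Jacobian at the optimum."""
        fit = fit_learning_curve(healthy_all_series)
        theta = np.array(fit.params.as_tuple())
        x, y = healthy_all_series.trials, healthy_all_series.counts

        def predict(t):
            return evaluate_model(ModelParams(*t), x)

        J = np.empty((5, 3))
        h = 1e-6
        for j in range(3):
            up, dn = theta.copy(), theta.copy()
            up[j] += h * max(1, abs(theta[j]))
            dn[j] -= h * max(1, abs(theta[j]))
            J[:, j] = (predict(up) - predict(dn)) / (up[j] - dn[j])
        resid = y - predict(theta)
        s2 = resid @ resid / (5 - 3)
        cov = s2 * np.linalg.inv(J.T @ J)
        se_oracle = np.sqrt(np.diag(cov))
        se_fit = np.array([fit.se[k] for k in ("B2", "B3", "B4")])
        assert np.allclose(se_fit, se_oracle, rtol=1e-4)

    def test_model_r2_beats_line_on_model_data(self):
        """The 3-parameter curve fits its own data at least as well as a line."""
        truth = ModelParams(0.6, 5.0, 13.0)
        y = evaluate_model(truth, X5)
        series = RecallSeries(X5, y)
        fit = fit_learning_curve(series)
        slope, icept = np.polyfit(X5, y, 1)
        line_res = y - (slope * X5 + icept)
        line_r2 = 1 - line_res @ line_res / np.sum((y - y.mean()) ** 2)
        assert fit.r_squared >= line_r2

    def test_flat_noisy_curve_flags_unreliable_b2(self):
        """B3 ~ B4 makes the learning rate unidentifiable; the fit says so."""
        fit = fit_learning_curve(_series([7, 8, 7, 8, 7]))
        assert fit.converged
        assert fit.b2_unreliable


class TestCompareCoefficients:
    def test_identical_fits_give_null_result(self):
        f = _make_fit(0.6, 7.0, 13.0, (0.05, 0.2, 0.3))
        res = compare_coefficients(f, f, "B3")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_normal_quantile_identity(self):
        se = (0.05, 0.2, 0.3)
        delta = 1.96 * np.hypot(0.2, 0.2)
        a = _make_fit(0.6, 7.0 + delta, 13.0, se)
        b = _make_fit(0.6, 7.0, 13.0, se)
        res = compare_coefficients(a, b, "B3")
        assert res.p_value == pytest.approx(0.05, abs=1e-3)

    def test_published_female_vs_male_b3_direction(self):
        """Healthy females' readiness to learn exceeds males' (B3 7.63 vs 5.90)."""
        females = _make_fit(0.70, 7.63, 14.38, (0.07, 0.15, 0.23))
        males = _make_fit(0.47, 5.90, 13.58, (0.06, 0.17, 0.48))
        res = compare_coefficients(females, males, "B3")
        assert res.statistic == pytest.approx(7.63, abs=0.01)
        assert res.statistic > 0
        assert res.p_value < 0.01

    def test_zero_se_rejected(self):
        good = _make_fit(0.6, 7.0, 13.0, (0.05, 0.2, 0.3))
        bad = _make_fit(0.6, 7.0, 13.0, (0.05, 0.0, 0.3))
        with pytest.raises(DegenerateComparisonError):
            compare_coefficients(good, bad, "B3")


class TestDerivedSummaries:
    @pytest.mark.parametrize(
        "counts, expected",
        [([2, 4, 6, 8, 10], 2.0), ([5, 5, 5, 5, 5], 0.0),
         (GROUP_TRIAL_MEANS["healthy_all"], 1.542)],
    )
    def test_learning_slope(self, counts, expected):
        assert learning_slope(_series(counts)) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "counts, expected",
        [([5, 8, 10, 9, 11], 6.0), ([12, 10, 9, 8, 7], 0.0),
         (GROUP_TRIAL_MEANS["healthy_male_lower"], 6.56)],
    )
    def test_max_minus_first(self, counts, expected):
        assert max_minus_first(_series(counts)) == pytest.approx(expected)

    def test_slope_needs_two_trials(self):
        with pytest.raises(InputError):
            learning_slope(RecallSeries.from_counts([7]))
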