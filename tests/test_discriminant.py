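"""Fisher LDA: conventions, Wilks/Bartlett, classification, cutoffs."""

import numpy as np
import pytest

from cvltcurve import (
    CollinearityError,
    DegenerateComparisonError,
    DiscriminantModel,
    InputError,
    bartlett_chi2,
    classify,
    classify_many,
    compare_group_means,
    fit_lda,
    threshold_from_function,
    verify_holdout,
)
from cvltcurve.reference_data import (
    PUBLISHED_CUTOFFS,
    UNIVARIATE_DISCRIMINANTS,
    WILKS_TESTS,
)


def _univariate_groups(mean_a=8.0, mean_b=4.0):
    """Equal-size univariate groups with pooled SD exactly 1."""
    dev = np.array([-1.0, 0.0, 1.0])  # W = 4, N - g = 4 -> pooled var 1
    return (mean_a + dev)[:, None], (mean_b + dev)[:, None]


class TestConventions:
    def test_symmetric_univariate_midpoint(self):
        A, B = _univariate_groups(8.0, 4.0)
        m = fit_lda(A, B)
        assert m.weights[0] == pytest.approx(1.0)
        cutoff = threshold_from_function(m.constant, float(m.weights[0]), m.boundary)
        assert cutoff == pytest.approx(6.0)

    def test_score_scaling_and_centering(self, rng):
        """Pooled within-group score variance 1; weighted grand mean 0."""
        A = rng.normal([10, 12], [1.5, 2.0], (25, 2))
        B = rng.normal([7, 9], [1.5, 2.0], (40, 2))
        m = fit_lda(A, B)
        sa, sb = m.score(A), m.score(B)
        pooled = (np.sum((sa - sa.mean()) ** 2) + np.sum((sb - sb.mean()) ** 2)) / (
            len(A) + len(B) - 2
        )
        assert pooled == pytest.approx(1.0, abs=1e-9)
        grand = (sa.sum() + sb.sum()) / (len(A) + len(B))
        assert grand == pytest.approx(0.0, abs=1e-9)
        assert m.centroids[0] > m.centroids[1]
        assert m.centroids[1] < m.boundary < m.centroids[0]

    def test_equal_n_univariate_cutoff_is_mean_midpoint(self, rng):
        a = rng.normal(11.0, 1.0, 20)
        b = rng.normal(6.0, 1.0, 20)
        m = fit_lda(a[:, None], b[:, None])
        cutoff = threshold_from_function(m.constant, float(m.weights[0]), m.boundary)
        assert cutoff == pytest.approx((a.mean() + b.mean()) / 2, abs=1e-9)

    def test_direction_matches_angle_grid_oracle(self, rng):
        """2-D: weights align with the 1-degree-grid Fisher-ratio maximizer."""
        A = rng.multivariate_normal([10, 8], [[2, 0.8], [0.8, 1]], 60)
        B = rng.multivariate_normal([7, 6.5], [[2, 0.8], [0.8, 1]], 60)
        m = fit_lda(A, B)

        def fisher_ratio(theta):
            w = np.array([np.cos(theta), np.sin(theta)])
            pa, pb = A @ w, B @ w
            between = (pa.mean() - pb.mean()) ** 2
            within = np.sum((pa - pa.mean()) ** 2) + np.sum((pb - pb.mean()) ** 2)
            return between / within

        grid = np.deg2rad(np.arange(0, 180))
        best = grid[np.argmax([fisher_ratio(t) for t in grid])]
        w_best = np.array([np.cos(best), np.sin(best)])
        w_fit = m.weights / np.linalg.norm(m.weights)
        angle = np.degrees(np.arccos(np.clip(abs(w_fit @ w_best), -1, 1)))
        assert angle <= 1.0

    def test_matches_sklearn_direction(self, rng):
        sklearn_lda = pytest.importorskip("sklearn.discriminant_analysis")
        A = rng.normal([9, 11, 12, 13, 14], 1.2, (30, 5))
        B = rng.normal([6, 8, 9, 10, 10], 1.2, (30, 5))
        m = fit_lda(A, B)
        clf = sklearn_lda.LinearDiscriminantAnalysis(solver="eigen")
        clf.fit(np.vstack([A, B]), np.r_[np.ones(30), np.zeros(30)])
        w_sk = clf.coef_.ravel()
        cos = abs(w_sk @ m.weights) / (np.linalg.norm(w_sk) * np.linalg.norm(m.weights))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_collinear_predictors_rejected(self, rng):
        A = rng.normal(10, 1, (10, 1))
        B = rng.normal(6, 1, (10, 1))
        A2 = np.hstack([A, 2 * A])
        B2 = np.hstack([B, 2 * B])
        with pytest.raises(CollinearityError):
            fit_lda(A2, B2)

    def test_group_too_small_rejected(self):
        with pytest.raises(InputError):
            fit_lda(np.ones((2, 1)) + [[0], [1]], np.zeros((5, 1)))


class TestWilksBartlett:
    def test_no_separation_limit(self):
        assert bartlett_chi2(1.0, 100, 5) == 0.0

    @pytest.mark.parametrize("case", WILKS_TESTS, ids=lambda c: c["name"])
    def test_reconciles_published_chi_square(self, case):
        """Bartlett's formula reproduces every published chi-square from its
        published lambda and group sizes (slack: rounding of lambda)."""
        chi2 = bartlett_chi2(
            case["wilks_lambda"], case["n_a"] + case["n_b"], case["p"]
        )
        assert chi2 == pytest.approx(case["chi2"], abs=0.5)

    def test_lambda_equals_within_over_total(self, rng):
        a = rng.normal(10, 1.0, 30)
        b = rng.normal(8, 1.0, 40)
        m = fit_lda(a[:, None], b[:, None])
        both = np.r_[a, b]
        W = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
        T = np.sum((both - both.mean()) ** 2)
        assert m.wilks_lambda == pytest.approx(W / T, abs=1e-12)


class TestClassification:
    def _male_b3_model(self):
        fn = UNIVARIATE_DISCRIMINANTS["male_b3"]
        return DiscriminantModel(
            constant=fn["constant"],
            weights=np.array([fn["weight"]]),
            boundary=fn["boundary"],
            wilks_lambda=0.406,
            chi2=50.958,
            df=1,
            p_value=1e-12,
            centroids=(2.0, -1.0),
            n_per_group=(11, 48),
            group_names=("healthy-like", "impaired"),
        )

    def test_boundary_inclusive_on_unimpaired_side(self):
        m = self._male_b3_model()
        x_at_boundary = (m.boundary - m.constant) / m.weights[0]
        label, score = classify(m, [x_at_boundary])
        assert score == pytest.approx(m.boundary)
        assert label == "healthy-like"

    def test_published_borderline_patient_classified_impaired(self):
        """B3 = 5.64 falls on the impaired side of the published male model."""
        label, _ = classify(self._male_b3_model(), [5.64])
        assert label == "impaired"

    def test_invariant_to_positive_rescaling(self, rng):
        m = self._male_b3_model()
        scaled = DiscriminantModel(
            constant=m.constant * 3.7,
            weights=m.weights * 3.7,
            boundary=m.boundary * 3.7,
            wilks_lambda=m.wilks_lambda,
            chi2=m.chi2,
            df=m.df,
            p_value=m.p_value,
            centroids=m.centroids,
            n_per_group=m.n_per_group,
            group_names=m.group_names,
        )
        xs = rng.uniform(0, 12, (50, 1))
        assert list(classify_many(m, xs).labels) == list(classify_many(scaled, xs).labels)

    def test_holdout_counts(self):
        m = self._male_b3_model()
        cutoff = threshold_from_function(m.constant, float(m.weights[0]), m.boundary)
        holdout = np.linspace(cutoff - 2, cutoff + 2, 9)[:, None]
        rep = verify_holdout(m, holdout, "healthy-like")
        assert rep.n_matching == int(np.sum(holdout.ravel() >= cutoff))
        assert rep.percent_matching == pytest.approx(100 * rep.n_matching / 9)

    def test_training_reference_group_classified_healthy(self, rng):
        a = rng.normal(11, 1.0, 15)
        b = rng.normal(5, 1.0, 15)
        m = fit_lda(a[:, None], b[:, None], group_names=("healthy-like", "impaired"))
        label, _ = classify(m, [a.mean()])
        assert label == "healthy-like"


class TestCutoffInversion:
    @pytest.mark.parametrize("key", sorted(PUBLISHED_CUTOFFS))
    def test_published_functions_invert_to_published_cutoffs(self, key):
        fn = UNIVARIATE_DISCRIMINANTS[key]
        cutoff = threshold_from_function(fn["constant"], fn["weight"], fn["boundary"])
        assert cutoff == pytest.approx(PUBLISHED_CUTOFFS[key], abs=0.01)

    def test_identity_function(self):
        assert threshold_from_function(0.0, 1.0, 0.0) == 0.0

    def test_zero_weight_rejected(self):
        with pytest.raises(DegenerateComparisonError):
            threshold_from_function(1.0, 0.0, 0.5)


class TestGroupMeanTests:
    def test_identical_groups_null(self):
        X = np.arange(10, dtype=float).reshape(5, 2)
        for t, p in compare_group_means(X, X):
            assert t == pytest.approx(0.0, abs=1e-12)
            assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a = np.array([[10.0], [12.0], [14.0]])
        b = np.array([[7.0], [9.0], [8.0]])
        (t, p), = compare_group_means(a, b)
        sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(float(t_hand))

    def test_antisymmetry(self, rng):
        A = rng.normal(10, 1, (8, 3))
        B = rng.normal(8, 1, (8, 3))
        fwd = compare_group_means(A, B)
        rev = compare_group_means(B, A)
        for (t1, p1), (t2, p2) in zip(fwd, rev):
            assert t1 == pytest.approx(-t2)
            assert p1 == pytest.approx(p2)
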