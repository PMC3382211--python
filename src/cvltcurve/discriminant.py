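"""Fisher linear discriminant analysis between two groups.

Used either univariately (on the learning-curve coefficient B3 or B4) or
with the five raw trial scores entered together. Conventions follow the
canonical two-group discriminant output of the major statistics packages:

* weights proportional to S_pooled^-1 (mean_a - mean_b), rescaled so the
  pooled within-group variance of discriminant scores is exactly 1;
* the constant set so the size-weighted grand mean score is 0;
* sign fixed so the first (reference, e.g. healthy) group has the larger
  centroid;
* the boundary value Y_b is the unweighted midpoint of the two group
  centroids (a size-weighted variant is available); scores >= Y_b classify
  as the reference group;
* separation is tested with Wilks' lambda = |W| / |T| and Bartlett's
  chi-square approximation  chi2 = -(N - 1 - (p + g)/2) * ln(lambda)  on
  p(g - 1) degrees of freedom.

A univariate discriminant function  y = C0 + C1 * B  inverts to a cutoff on
the predictor scale,  B_cut = (Y_b - C0) / C1 : patients below the cutoff
classify as memory-impaired (:func:`threshold_from_function`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CollinearityError, DegenerateComparisonError, InputError

__all__ = [
    "DiscriminantModel",
    "ClassificationReport",
    "fit_lda",
    "classify",
    "classify_many",
    "threshold_from_function",
    "verify_holdout",
    "compare_group_means",
    "bartlett_chi2",
]


@dataclass(frozen=True)
class DiscriminantModel:
    """A fitted two-group linear discriminant function."""

    constant: float
    weights: np.ndarray
    boundary: float
    wilks_lambda: float
    chi2: float
    df: int
    p_value: float
    centroids: tuple[float, float]  # (reference group, comparison group)
    n_per_group: tuple[int, int]
    group_names: tuple[str, str] = ("reference", "comparison")

    def score(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != len(self.weights):
            raise InputError(
                f"predictor has {x.shape[-1]} columns, model expects {len(self.weights)}"
            )
        s = self.constant + x @ self.weights
        return float(s) if s.ndim == 0 else s


@dataclass(frozen=True)
class ClassificationReport:
    """Outcome of classifying a set of subjects with a discriminant model."""

    scores: np.ndarray
    labels: np.ndarray
    counts: dict[str, int]
    expected_label: str | None = None

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def n_matching(self) -> int:
        if self.expected_label is None:
            raise InputError("no expected label set for this report")
        return self.counts.get(self.expected_label, 0)

    @property
    def percent_matching(self) -> float:
        return 100.0 * self.n_matching / self.n


def bartlett_chi2(wilks_lambda: float, n_total: int, p: int, g: int = 2) -> float:
    """Bartlett's chi-square approximation for Wilks' lambda."""
    if not 0 < wilks_lambda <= 1:
        raise InputError(f"Wilks' lambda must be in (0, 1], got {wilks_lambda}")
    return float(-(n_total - 1 - (p + g) / 2.0) * np.log(wilks_lambda))


def _as_matrix(X, name):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise InputError(f"{name} must be a vector or 2-D matrix")
    if not np.isfinite(X).all():
        raise InputError(f"{name} contains non-finite values")
    return X


def fit_lda(
    group_a,
    group_b,
    group_names: tuple[str, str] = ("reference", "comparison"),
    boundary: str = "midpoint",
) -> DiscriminantModel:
    """Fit a two-group Fisher discriminant function.

    Parameters
    ----------
    group_a, group_b : array-like, (n_a, p) and (n_b, p)
        The reference (e.g. healthy higher-functioning cluster) and
        comparison (e.g. patient lower-functioning cluster) groups. A 1-D
        array is treated as a single predictor.
    group_names : pair of str
        Labels attached to the two groups; ``classify`` returns
        ``group_names[0]`` for scores at or above the boundary.
    boundary : {"midpoint", "weighted"}
        Unweighted midpoint of the two centroids (default) or the
        size-weighted mean of the centroids.
    """
    A = _as_matrix(group_a, "group_a")
    B = _as_matrix(group_b, "group_b")
    if A.shape[1] != B.shape[1]:
        raise InputError("groups have different numbers of predictors")
    p = A.shape[1]
    n_a, n_b = len(A), len(B)
    if n_a < p + 2 or n_b < p + 2:
        raise InputError(
            f"each group needs at least p + 2 = {p + 2} subjects (got {n_a}, {n_b})"
        )
    N, g = n_a + n_b, 2

    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - mean_a, B - mean_b
    W = Ac.T @ Ac + Bc.T @ Bc  # within-group cross-products
    S_pooled = W / (N - g)

    cond = np.linalg.cond(S_pooled)
    if not np.isfinite(cond) or cond > 1e12:
        variances = np.diag(S_pooled)
        bad = [f"x{i + 1}" for i, v in enumerate(variances) if v <= 1e-12]
        detail = f"near-constant predictors: {', '.join(bad)}" if bad else (
            "predictors are collinear"
        )
        raise CollinearityError(
            f"pooled within-group covariance is singular ({detail})"
        )

    w = np.linalg.solve(S_pooled, mean_a - mean_b)
    scale = float(w @ S_pooled @ w)
    if scale <= 0:
        raise CollinearityError("degenerate discriminant direction")
    w = w / np.sqrt(scale)  # pooled within-group score variance = 1
    if w @ (mean_a - mean_b) < 0:
        w = -w  # reference group scores higher

    raw_a, raw_b = float(w @ mean_a), float(w @ mean_b)
    constant = -(n_a * raw_a + n_b * raw_b) / N  # grand weighted mean -> 0
    cent_a, cent_b = raw_a + constant, raw_b + constant
    if boundary == "midpoint":
        y_b = 0.5 * (cent_a + cent_b)
    elif boundary == "weighted":
        y_b = (n_a * cent_a + n_b * cent_b) / N
    else:
        raise InputError(f"unknown boundary convention {boundary!r}")

    grand = (n_a * mean_a + n_b * mean_b) / N
    allX = np.vstack([A, B]) - grand
    T = allX.T @ allX
    if p == 1:
        lam = float(W[0, 0] / T[0, 0]) if T[0, 0] > 0 else 1.0
    else:
        sign_w, logdet_w = np.linalg.slogdet(W)
        sign_t, logdet_t = np.linalg.slogdet(T)
        lam = float(np.exp(logdet_w - logdet_t)) if sign_w > 0 and sign_t > 0 else 1.0
    lam = min(lam, 1.0)
    chi2 = bartlett_chi2(lam, N, p, g)
    df = p * (g - 1)
    p_value = float(stats.chi2.sf(chi2, df))

    return DiscriminantModel(
        constant=float(constant),
        weights=w,
        boundary=float(y_b),
        wilks_lambda=lam,
        chi2=chi2,
        df=df,
        p_value=p_value,
        centroids=(float(cent_a), float(cent_b)),
        n_per_group=(n_a, n_b),
        group_names=group_names,
    )


def classify(model: DiscriminantModel, x) -> tuple[str, float]:
    """Score one predictor vector; >= boundary means the reference group.

    The boundary is inclusive on the reference (unimpaired) side: a score
    exactly at Y_b classifies as no memory impairment.
    """
    s = model.score(np.atleast_1d(np.asarray(x, dtype=float)))
    s = float(np.asarray(s).ravel()[0])
    label = model.group_names[0] if s >= model.boundary else model.group_names[1]
    return label, s


def classify_many(model: DiscriminantModel, X) -> ClassificationReport:
    """Classify every row of ``X``; report scores, labels and counts."""
    X = _as_matrix(X, "X")
    scores = model.score(X)
    labels = np.where(
        scores >= model.boundary, model.group_names[0], model.group_names[1]
    ).astype(str)
    counts = {name: int((labels == name).sum()) for name in model.group_names}
    return ClassificationReport(scores=scores, labels=labels, counts=counts)


def threshold_from_function(c0: float, c1: float, boundary: float) -> float:
    """Invert a univariate discriminant function at its boundary.

    Returns the predictor cutoff (boundary - c0) / c1. For c1 > 0,
    predictor values below the cutoff classify as impaired.
    """
    if c1 == 0:
        raise DegenerateComparisonError("univariate weight is 0; no cutoff exists")
    return (boundary - c0) / c1


def verify_holdout(model: DiscriminantModel, holdout, expected_label: str) -> ClassificationReport:
    """Classify a held-out cluster and count agreement with ``expected_label``."""
    if expected_label not in model.group_names:
        raise InputError(
            f"expected label {expected_label!r} not one of {model.group_names}"
        )
    rep = classify_many(model, holdout)
    return ClassificationReport(
        scores=rep.scores,
        labels=rep.labels,
        counts=rep.counts,
        expected_label=expected_label,
    )


def compare_group_means(group_a_trials, group_b_trials):
    """Per-trial pooled-variance independent-samples t-tests (two-sided).

    Returns a list of (t, p) pairs, one per column.
    """
    A = _as_matrix(group_a_trials, "group_a_trials")
    B = _as_matrix(group_b_trials, "group_b_trials")
    if A.shape[1] != B.shape[1]:
        raise InputError("groups have different numbers of trials")
    if len(A) < 2 or len(B) < 2:
        raise InputError("each group needs at least 2 subjects")
    out = []
    for j in range(A.shape[1]):
        a, b = A[:, j], B[:, j]
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            if a.mean() == b.mean():
                out.append((0.0, 1.0))
                continue
            raise DegenerateComparisonError(
                f"trial {j + 1}: zero pooled variance with unequal means"
            )
        t, pv = stats.ttest_ind(a, b, equal_var=True)
        out.append((float(t), float(pv)))
    return out
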