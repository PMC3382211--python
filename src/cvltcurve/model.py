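"""First-order transfer-function model of the verbal learning curve.

The number of words recalled on trial ``X`` of a repeated free-recall test
(CVLT-II List A: 16 words, five trials) is modelled as the step response of
a first-order system,

    Y(X) = B3 * exp(-B2 * (X - 1)) + B4 * (1 - exp(-B2 * (X - 1))),

where

* ``B3`` ("readiness to learn") is the predicted recall on trial 1 — the
  model passes exactly through B3 at X = 1 — a proxy for attention span and
  short-term memory encoding;
* ``B4`` ("ability to learn") is the asymptotic recall as X grows — a proxy
  for long-term memory consolidation;
* ``B2`` ("learning rate") is the inverse time constant: 1/B2 is the number
  of trials (after trial 1) needed to cover 63% of the gap between B3 and B4.

Coefficients are estimated per subject (or per averaged group curve) by
nonlinear least squares; asymptotic standard errors come from the
Gauss-Newton curvature of the residual surface, scaled by the residual
variance with n - 3 degrees of freedom, and goodness of fit is the usual
R^2 = 1 - SS_res / SS_tot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateComparisonError, InputError, ParameterError

__all__ = [
    "ModelParams",
    "RecallSeries",
    "ModelFit",
    "CoefficientComparison",
    "evaluate_model",
    "fit_learning_curve",
    "compare_coefficients",
    "learning_slope",
    "max_minus_first",
    "DEFAULT_MAX_SCORE",
]

#: Number of words in CVLT-II List A; recall counts live in [0, 16].
DEFAULT_MAX_SCORE = 16

#: Restart grid for the learning rate when the default start fails.
_B2_STARTS = (0.5, 0.1, 1.0, 2.0)

COEFFICIENT_NAMES = ("B2", "B3", "B4")


@dataclass(frozen=True)
class ModelParams:
    """Coefficients of the learning-curve model.

    Attributes
    ----------
    b2 : float
        Learning rate per trial (inverse time constant); must be > 0.
    b3 : float
        Predicted recall on trial 1, in words; must be >= 0.
    b4 : float
        Asymptotic recall, in words; must be >= 0.
    """

    b2: float
    b3: float
    b4: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.b2, self.b3, self.b4]).all():
            raise ParameterError("model coefficients must be finite")
        if self.b2 <= 0:
            raise ParameterError(f"learning rate B2 must be > 0, got {self.b2}")
        if self.b3 < 0 or self.b4 < 0:
            raise ParameterError(
                f"recall levels B3, B4 must be >= 0, got B3={self.b3}, B4={self.b4}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.b2, self.b3, self.b4)

    def __getitem__(self, name: str) -> float:
        try:
            return {"B2": self.b2, "B3": self.b3, "B4": self.b4}[name.upper()]
        except KeyError:
            raise KeyError(f"unknown coefficient {name!r}; expected B2, B3 or B4")


@dataclass(frozen=True)
class RecallSeries:
    """One subject's trial-indexed free-recall counts.

    ``trials`` are the strictly increasing trial numbers (the model's X,
    starting at 1) and ``counts`` the words recalled on each trial (the
    model's Y). Counts may be real-valued: averaged group curves are fit to
    per-trial means. Per-subject raw data should be integers; that check is
    enforced at the cohort-table layer, not here.
    """

    trials: np.ndarray
    counts: np.ndarray
    max_score: int = DEFAULT_MAX_SCORE

    def __post_init__(self) -> None:
        trials = np.asarray(self.trials, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "trials", trials)
        object.__setattr__(self, "counts", counts)
        if trials.ndim != 1 or counts.ndim != 1 or len(trials) != len(counts):
            raise InputError("trials and counts must be 1-D arrays of equal length")
        if len(trials) == 0:
            raise InputError("empty recall series")
        if not np.isfinite(trials).all() or not np.isfinite(counts).all():
            raise InputError("recall series contains non-finite values")
        if np.any(np.diff(trials) <= 0):
            raise InputError("trial numbers must be strictly increasing")
        if trials[0] < 1:
            raise InputError("trial numbers start at 1")
        if np.any(counts < 0) or np.any(counts > self.max_score):
            raise InputError(
                f"recall counts must lie in [0, {self.max_score}], got "
                f"range [{counts.min()}, {counts.max()}]"
            )

    @classmethod
    def from_counts(cls, counts, max_score: int = DEFAULT_MAX_SCORE) -> "RecallSeries":
        """Build a series from counts alone, trials numbered 1..n."""
        counts = np.asarray(counts, dtype=float)
        return cls(np.arange(1, len(counts) + 1, dtype=float), counts, max_score)

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class ModelFit:
    """Result of a nonlinear least-squares fit of the learning-curve model."""

    params: ModelParams | None
    se: dict[str, float]
    r_squared: float
    residuals: np.ndarray
    converged: bool
    n_points: int
    #: True when the B2 standard error exceeds the B2 estimate — the flat-curve
    #: pathology where B3 ~ B4 makes the learning rate unidentifiable.
    b2_unreliable: bool = False
    message: str = ""

    def coefficient(self, name: str) -> float:
        if self.params is None:
            raise InputError("fit did not converge; no coefficients available")
        return self.params[name]


@dataclass(frozen=True)
class CoefficientComparison:
    """Wald comparison of one coefficient between two independent fits."""

    statistic: float
    p_value: float
    difference: float
    se_difference: float


def evaluate_model(params: ModelParams, x) -> np.ndarray | float:
    """Predicted recall at trial number(s) ``x`` (x >= 1, real-valued).

    At x = 1 this returns exactly B3; as x -> infinity it approaches B4.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 1):
        raise InputError("trial number x must be >= 1")
    decay = np.exp(-params.b2 * (x_arr - 1.0))
    out = params.b3 * decay + params.b4 * (1.0 - decay)
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def _curve(x, b2, b3, b4):
    decay = np.exp(-b2 * (x - 1.0))
    return b3 * decay + b4 * (1.0 - decay)


def fit_learning_curve(
    series: RecallSeries,
    init: ModelParams | None = None,
    bounds: tuple | None = None,
) -> ModelFit:
    """Least-squares fit of (B2, B3, B4) to one recall series.

    Parameters
    ----------
    series : RecallSeries
        At least 3 distinct trials (the model has 3 free parameters).
    init : ModelParams, optional
        Starting values. Default: B3 = first count, B4 = last count,
        B2 = 0.5; on failure a small grid of B2 starts is tried and the
        best (lowest SSE) successful fit kept.
    bounds : ((lo_b2, lo_b3, lo_b4), (hi_b2, hi_b3, hi_b4)), optional
        Box constraints. Default: B2 in (1e-4, 10], B3 in [0, max_score],
        B4 in [0, max_score + 4] — the asymptote gets headroom above the
        ceiling so near-ceiling learners are not censored.

    Returns
    -------
    ModelFit
        ``converged`` is False (with params=None) if every start fails;
        a failed fit is reported, never silently fabricated.
    """
    x = series.trials
    y = series.counts
    if len(np.unique(x)) < 3:
        raise InputError("need at least 3 distinct trials to fit 3 coefficients")

    if bounds is None:
        hi = float(series.max_score)
        bounds = ((1e-4, 0.0, 0.0), (10.0, hi, hi + 4.0))
    lo, hi_b = (np.asarray(b, dtype=float) for b in bounds)

    def clipped_start(b2, b3, b4):
        p = np.clip([b2, b3, b4], lo, hi_b)
        return tuple(p)

    if init is not None:
        starts = [clipped_start(init.b2, init.b3, init.b4)]
    else:
        starts = [clipped_start(b2, y[0], y[-1]) for b2 in _B2_STARTS]

    best = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                _curve, x, y, p0=p0, bounds=(lo, hi_b), maxfev=10_000
            )
        except (RuntimeError, optimize.OptimizeWarning, ValueError):
            continue
        sse = float(np.sum((y - _curve(x, *popt)) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, popt, pcov)

    n = len(x)
    if best is None:
        return ModelFit(
            params=None,
            se={k: np.nan for k in COEFFICIENT_NAMES},
            r_squared=np.nan,
            residuals=np.full(n, np.nan),
            converged=False,
            n_points=n,
            message="no start point converged",
        )

    sse, popt, pcov = best
    params = ModelParams(*popt)
    residuals = y - _curve(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - sse / ss_tot if ss_tot > 0 else (1.0 if sse == 0 else np.nan)
    # curve_fit already scales cov by SSE / (n - p): asymptotic SEs.
    diag = np.diag(pcov)
    se_vals = np.sqrt(np.where(np.isfinite(diag) & (diag >= 0), diag, np.nan))
    se = dict(zip(COEFFICIENT_NAMES, (float(s) for s in se_vals)))
    b2_unreliable = bool(np.isnan(se["B2"]) or se["B2"] > params.b2)
    return ModelFit(
        params=params,
        se=se,
        r_squared=float(r_squared),
        residuals=residuals,
        converged=True,
        n_points=n,
        b2_unreliable=b2_unreliable,
    )


def compare_coefficients(
    fit_a: ModelFit, fit_b: ModelFit, which: str
) -> CoefficientComparison:
    """Wald z-test for a coefficient difference between two independent fits.

    z = (b_a - b_b) / sqrt(se_a^2 + se_b^2), two-sided p from the standard
    normal. The normal reference (rather than t) is used because the fits
    come from separate small samples with no shared error variance; the test
    surface is direction of effect and significance level, not exact p.
    """
    which = which.upper()
    if which not in COEFFICIENT_NAMES:
        raise KeyError(f"unknown coefficient {which!r}")
    if not (fit_a.converged and fit_b.converged):
        raise DegenerateComparisonError("both fits must have converged")
    se_a, se_b = fit_a.se[which], fit_b.se[which]
    if not (np.isfinite(se_a) and np.isfinite(se_b)) or se_a <= 0 or se_b <= 0:
        raise DegenerateComparisonError(
            f"cannot compare {which}: standard errors must be positive "
            f"(got {se_a}, {se_b})"
        )
    diff = fit_a.coefficient(which) - fit_b.coefficient(which)
    se_diff = float(np.hypot(se_a, se_b))
    z = diff / se_diff
    p = 2.0 * stats.norm.sf(abs(z))
    return CoefficientComparison(
        statistic=float(z), p_value=float(p), difference=float(diff), se_difference=se_diff
    )


def learning_slope(series: RecallSeries) -> float:
    """Ordinary least-squares slope of recall on trial number (words/trial).

    The CVLT-II "learning slope" summary; misleading near ceiling, which is
    why the model's B2 exists, but kept for comparison.
    """
    if len(series) < 2:
        raise InputError("need at least 2 trials for a slope")
    if np.ptp(series.trials) == 0:
        raise InputError("trial numbers are constant")
    slope, _ = np.polyfit(series.trials, series.counts, 1)
    return float(slope)


def max_minus_first(series: RecallSeries) -> float:
    """Y_max - Y_1: best recall over all trials minus trial-1 recall."""
    return float(series.counts.max() - series.counts[0])
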