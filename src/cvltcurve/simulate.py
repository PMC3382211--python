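"""Synthetic cohort generator with the latent structure the analysis assumes.

Each sex x diagnosis cell is a two-component mixture of ``lower`` and
``higher`` memory-functioning subgroups. A subject's true learning-curve
coefficients (B2, B3, B4) are drawn from truncated normals around the
subgroup means; the five trial scores are the model curve evaluated at
trials 1..5 plus per-trial observation noise, rounded and clipped to the
0-16 word range of CVLT-II List A.

Default subgroup means are the published averaged-curve coefficients of the
B3-based two-means clusters (see :mod:`cvltcurve.reference_data`), so the
default cohort reproduces the study conditions: e.g. the MS-male lower
subgroup learns from B3 ~ 4.26 toward B4 ~ 9.81 while the healthy-male
higher subgroup runs from 7.50 toward 13.46. Because the study reported
only standard errors of averaged-curve fits, not population dispersions,
between-subject SDs default to 1.0 word for B3/B4; B2 gets 0.15 (a 1.0-word
SD has no meaning for a rate with mean ~0.65 bounded at zero). Observation
noise defaults to SD 1.0 word per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .model import DEFAULT_MAX_SCORE, ModelParams, RecallSeries, evaluate_model, fit_learning_curve
from .reference_data import SUBGROUP_CURVE_PARAMS

__all__ = [
    "SubgroupSpec",
    "CellSpec",
    "PopulationSpec",
    "default_spec",
    "generate_cohort",
    "recovery_report",
    "TRUTH_COLUMNS",
]

SEXES = ("F", "M")
DIAGNOSES = ("control", "patient")
SUBGROUPS = ("lower", "higher")

#: Columns of the latent-truth sidecar table.
TRUTH_COLUMNS = ["subject_id", "subgroup", "B2", "B3", "B4"]

#: Coefficient bounds used when truncating draws (match the fit bounds).
_B2_RANGE = (1e-4, 10.0)


@dataclass(frozen=True)
class SubgroupSpec:
    """Generating distribution of one latent memory-functioning subgroup."""

    weight: float
    b2_mean: float
    b2_sd: float = 0.15
    b3_mean: float = 6.0
    b3_sd: float = 1.0
    b4_mean: float = 12.0
    b4_sd: float = 1.0
    noise_sd: float = 1.0

    def validate(self, max_score: int) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise InputError(f"subgroup weight must be in [0, 1], got {self.weight}")
        for name in ("b2_sd", "b3_sd", "b4_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if not _B2_RANGE[0] < self.b2_mean <= _B2_RANGE[1]:
            raise InputError(f"b2_mean out of range: {self.b2_mean}")
        if not 0 <= self.b3_mean <= max_score:
            raise InputError(f"b3_mean out of range: {self.b3_mean}")
        if not 0 <= self.b4_mean <= max_score + 4:
            raise InputError(f"b4_mean out of range: {self.b4_mean}")


@dataclass(frozen=True)
class CellSpec:
    """One sex x diagnosis cell: a lower/higher subgroup mixture."""

    lower: SubgroupSpec
    higher: SubgroupSpec

    def validate(self, max_score: int) -> None:
        self.lower.validate(max_score)
        self.higher.validate(max_score)
        if abs(self.lower.weight + self.higher.weight - 1.0) > 1e-9:
            raise InputError(
                "subgroup weights within a cell must sum to 1 "
                f"(got {self.lower.weight} + {self.higher.weight})"
            )


@dataclass(frozen=True)
class PopulationSpec:
    """Full generating specification: 4 cells x 2 subgroups.

    ``noise_model`` is ``"gaussian"`` (additive noise, rounded, clipped —
    default) or ``"binomial"`` (each of the 16 words recalled independently
    with probability mu/16, giving integer counts with mean mu directly).
    """

    cells: dict[tuple[str, str], CellSpec]
    max_score: int = DEFAULT_MAX_SCORE
    noise_model: str = "gaussian"

    def validate(self) -> None:
        if self.noise_model not in ("gaussian", "binomial"):
            raise InputError(f"unknown noise model {self.noise_model!r}")
        for key, cell in self.cells.items():
            if key[0] not in SEXES or key[1] not in DIAGNOSES:
                raise InputError(f"unknown cell {key!r}")
            cell.validate(self.max_score)


#: Observed lower-subgroup proportions: patients split about evenly; among
#: controls roughly 45% of males and 30% of females fall in the lower cluster.
_LOWER_WEIGHTS = {
    ("M", "control"): 0.45,
    ("F", "control"): 0.30,
    ("M", "patient"): 0.50,
    ("F", "patient"): 0.50,
}


def default_spec() -> PopulationSpec:
    """The study-calibrated default population specification."""
    cells = {}
    for sex in SEXES:
        for dx in DIAGNOSES:
            w_low = _LOWER_WEIGHTS[(sex, dx)]
            subs = {}
            for sub, weight in (("lower", w_low), ("higher", 1.0 - w_low)):
                ref = SUBGROUP_CURVE_PARAMS[(sex, dx, sub)]
                subs[sub] = SubgroupSpec(
                    weight=weight,
                    b2_mean=ref["B2"],
                    b3_mean=ref["B3"],
                    b4_mean=ref["B4"],
                )
            cells[(sex, dx)] = CellSpec(lower=subs["lower"], higher=subs["higher"])
    return PopulationSpec(cells=cells)


def _truncated_normal(rng, mean, sd, lo, hi, max_tries=1000):
    """Draw one value from N(mean, sd) restricted to (lo, hi] by resampling."""
    if sd == 0:
        if not lo < mean <= hi:
            raise InputError(f"degenerate draw {mean} outside ({lo}, {hi}]")
        return mean
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if lo < v <= hi:
            return v
    raise InputError(
        f"could not draw a value in ({lo}, {hi}] around {mean} +/- {sd}"
    )


def generate_cohort(
    spec: PopulationSpec | None = None,
    n_per_cell: int = 50,
    seed: int | None = 0,
    round_counts: bool = True,
) -> pd.DataFrame:
    """Generate a reproducible synthetic cohort.

    Parameters
    ----------
    spec : PopulationSpec, optional
        Defaults to :func:`default_spec`.
    n_per_cell : int
        Subjects per sex x diagnosis cell.
    seed : int
        Seed for the random generator; the same seed yields the identical
        cohort.
    round_counts : bool
        Round and clip trial scores to integer counts in [0, max_score]
        (the CVLT-II scale). Disable for noiseless parameter-recovery
        checks, where rounding alone would already perturb the curve.

    Returns
    -------
    DataFrame with columns subject_id, diagnosis, sex, latent_subgroup,
    B2_true, B3_true, B4_true, t1..t5.
    """
    if spec is None:
        spec = default_spec()
    spec.validate()
    if n_per_cell < 1:
        raise InputError("n_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    trials = np.arange(1, 6, dtype=float)

    rows = []
    counter = 0
    for sex in SEXES:
        for dx in DIAGNOSES:
            cell = spec.cells.get((sex, dx))
            if cell is None:
                continue
            for _ in range(n_per_cell):
                counter += 1
                sub = "lower" if rng.random() < cell.lower.weight else "higher"
                sg: SubgroupSpec = getattr(cell, sub)
                b2 = _truncated_normal(rng, sg.b2_mean, sg.b2_sd, *_B2_RANGE)
                b3 = _truncated_normal(rng, sg.b3_mean, sg.b3_sd, 0.0, spec.max_score)
                b4 = _truncated_normal(rng, sg.b4_mean, sg.b4_sd, 0.0, spec.max_score + 4.0)
                params = ModelParams(b2, b3, b4)
                mu = evaluate_model(params, trials)
                if spec.noise_model == "binomial":
                    pr = np.clip(mu / spec.max_score, 0.0, 1.0)
                    counts = rng.binomial(spec.max_score, pr).astype(float)
                else:
                    counts = mu + rng.normal(0.0, sg.noise_sd, size=5)
                    if round_counts:
                        counts = np.clip(np.round(counts), 0, spec.max_score)
                    else:
                        counts = np.clip(counts, 0, spec.max_score)
                rows.append(
                    {
                        "subject_id": f"S{counter:05d}",
                        "diagnosis": dx,
                        "sex": sex,
                        "latent_subgroup": sub,
                        "B2_true": b2,
                        "B3_true": b3,
                        "B4_true": b4,
                        **{f"t{i + 1}": counts[i] for i in range(5)},
                    }
                )
    return pd.DataFrame(rows)


def recovery_report(cohort: pd.DataFrame, max_score: int = DEFAULT_MAX_SCORE) -> dict:
    """Bias and RMSE of refitted coefficients against the generating truths.

    Fits every subject's curve and compares the estimates with the
    ``B*_true`` columns. Statistics are computed over converged fits only;
    the convergence rate is reported alongside.
    """
    required = {"B2_true", "B3_true", "B4_true"}
    if not required <= set(cohort.columns):
        raise InputError("cohort lacks latent truth columns; regenerate with truths")
    trial_cols = [f"t{i}" for i in range(1, 6)]
    est, truth = [], []
    n_failed = 0
    for _, row in cohort.iterrows():
        series = RecallSeries.from_counts(row[trial_cols].to_numpy(float), max_score)
        fit = fit_learning_curve(series)
        if not fit.converged:
            n_failed += 1
            continue
        est.append(fit.params.as_tuple())
        truth.append((row["B2_true"], row["B3_true"], row["B4_true"]))
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    n_ok = len(est)
    report: dict = {
        "n_subjects": len(cohort),
        "n_converged": n_ok,
        "convergence_rate": n_ok / len(cohort) if len(cohort) else np.nan,
        "coefficients": {},
    }
    for j, name in enumerate(("B2", "B3", "B4")):
        err = est[:, j] - truth[:, j] if n_ok else np.array([])
        report["coefficients"][name] = {
            "bias": float(err.mean()) if n_ok else np.nan,
            "rmse": float(np.sqrt((err**2).mean())) if n_ok else np.nan,
        }
    return report
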