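"""End-to-end memory-impairment analysis of a cohort table.

The full procedure, per sex stratum:

1. fit every subject's learning curve and form B3 and B4 samples;
2. split controls and patients each into lower/higher memory-functioning
   clusters by exact 1-D two-means on the coefficient;
3. train a univariate discriminant function on the control *higher* cluster
   versus the patient *lower* cluster (the clusters that best characterize
   each group), with boundary value, Wilks' lambda and Bartlett chi-square;
4. invert the function at its boundary into an impairment cutoff on the
   coefficient scale;
5. verify on the held-out clusters (control-lower, patient-higher);
6. for comparison, run the raw-trials variants: whole-group LDA on trials
   1-5 and LDA on Ward clusters of trials 1-5;
7. fit averaged learning curves per group and per cluster.

Input is a CSV cohort table with header
``subject_id,diagnosis,sex,t1,t2,t3,t4,t5``; output is a JSON-serializable
report plus a plain-text rendering. Subjects whose individual fit fails to
converge are excluded from coefficient-based analyses (but kept for the
raw-trials analyses) and counted in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import discriminant as da
from .errors import CvltCurveError, InputError, SchemaError
from .model import DEFAULT_MAX_SCORE, ModelFit, RecallSeries, fit_learning_curve
from .simulate import TRUTH_COLUMNS

__all__ = [
    "AnalysisConfig",
    "COHORT_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_truths_csv",
    "validate_cohort",
    "fit_averaged_curve",
    "fit_all_subjects",
    "run_full_analysis",
    "verify_report",
    "write_report",
    "render_report_text",
    "load_config",
]

log = logging.getLogger("cvltcurve")

COHORT_COLUMNS = ["subject_id", "diagnosis", "sex", "t1", "t2", "t3", "t4", "t5"]
TRIAL_COLS = ["t1", "t2", "t3", "t4", "t5"]
VALID_DIAGNOSES = {"control", "patient"}
VALID_SEXES = {"F", "M"}


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable settings of the full analysis.

    All fields are flat scalars so a config file is a flat YAML mapping.
    """

    max_score: int = DEFAULT_MAX_SCORE
    coefficients: tuple[str, ...] = ("B3", "B4")
    #: skip a sex stratum when either diagnosis group is smaller than this
    min_stratum_size: int = 6
    #: z-score trials 1-5 before Ward clustering (default raw: shared units)
    standardize_trials: bool = False
    #: "midpoint" (unweighted centroid midpoint) or "weighted"
    boundary: str = "midpoint"
    include_trials_lda: bool = True

    @classmethod
    def from_mapping(cls, data: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "coefficients" in data:
            data = {**data, "coefficients": tuple(data["coefficients"])}
        return cls(**data)


def load_config(path) -> AnalysisConfig:
    """Read a flat YAML mapping into an :class:`AnalysisConfig`."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError("config file must be a flat key/value mapping")
    return AnalysisConfig.from_mapping(data)


# ---------------------------------------------------------------- cohort I/O


def validate_cohort(df: pd.DataFrame, max_score: int = DEFAULT_MAX_SCORE) -> pd.DataFrame:
    """Validate the cohort schema; raise :class:`SchemaError` naming rows.

    Row numbers in messages are 1-based data rows (header excluded).
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required columns {missing}; expected {COHORT_COLUMNS}"
        )
    errors = []
    ids = df["subject_id"].astype(str)
    dup = ids[ids.duplicated()]
    for idx in dup.index:
        errors.append(f"row {idx + 1}: duplicate subject_id {ids[idx]!r}")
    for idx, val in df["diagnosis"].items():
        if val not in VALID_DIAGNOSES:
            errors.append(f"row {idx + 1}: diagnosis {val!r} not in {sorted(VALID_DIAGNOSES)}")
    for idx, val in df["sex"].items():
        if val not in VALID_SEXES:
            errors.append(f"row {idx + 1}: sex {val!r} not in {sorted(VALID_SEXES)}")
    for col in TRIAL_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx, v in vals.items():
            if pd.isna(v):
                errors.append(f"row {idx + 1}: {col} is not numeric")
            elif not (0 <= v <= max_score):
                errors.append(f"row {idx + 1}: {col}={v} outside [0, {max_score}]")
            elif float(v) != int(v):
                errors.append(f"row {idx + 1}: {col}={v} is not an integer count")
    if errors:
        raise SchemaError("invalid cohort table:\n" + "\n".join(errors))
    out = df[COHORT_COLUMNS].copy()
    out[TRIAL_COLS] = out[TRIAL_COLS].astype(int)
    out["subject_id"] = out["subject_id"].astype(str)
    return out.reset_index(drop=True)


def read_cohort_csv(path, max_score: int = DEFAULT_MAX_SCORE) -> pd.DataFrame:
    """Read and validate a cohort CSV (UTF-8, header required)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str})
    return validate_cohort(df, max_score=max_score)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write the cohort's schema columns to CSV."""
    df[COHORT_COLUMNS].to_csv(path, index=False)


def write_truths_csv(cohort: pd.DataFrame, path) -> None:
    """Write the latent-truth sidecar (subject_id, subgroup, B2, B3, B4)."""
    out = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"],
            "subgroup": cohort["latent_subgroup"],
            "B2": cohort["B2_true"],
            "B3": cohort["B3_true"],
            "B4": cohort["B4_true"],
        }
    )
    out.to_csv(path, index=False, columns=TRUTH_COLUMNS)


# ---------------------------------------------------------------- fitting


def fit_averaged_curve(subset: pd.DataFrame, max_score: int = DEFAULT_MAX_SCORE) -> ModelFit:
    """Fit the model to the per-trial means of a cohort subset."""
    if len(subset) == 0:
        raise InputError("cannot average an empty subset")
    means = subset[TRIAL_COLS].to_numpy(float).mean(axis=0)
    return fit_learning_curve(RecallSeries.from_counts(means, max_score))


def fit_all_subjects(cohort: pd.DataFrame, max_score: int = DEFAULT_MAX_SCORE) -> pd.DataFrame:
    """Fit each subject's curve; returns per-subject coefficient table.

    Columns: subject_id, converged, B2, B3, B4, r_squared (NaN where the
    fit failed).
    """
    rows = []
    for _, row in cohort.iterrows():
        series = RecallSeries.from_counts(row[TRIAL_COLS].to_numpy(float), max_score)
        fit = fit_learning_curve(series)
        rec = {"subject_id": row["subject_id"], "converged": fit.converged}
        if fit.converged:
            rec.update(
                B2=fit.params.b2, B3=fit.params.b3, B4=fit.params.b4,
                r_squared=fit.r_squared,
            )
        else:
            rec.update(B2=np.nan, B3=np.nan, B4=np.nan, r_squared=np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- reporting


def _fit_summary(fit: ModelFit) -> dict:
    if not fit.converged:
        return {"converged": False}
    return {
        "converged": True,
        "B2": fit.params.b2,
        "B3": fit.params.b3,
        "B4": fit.params.b4,
        "se": dict(fit.se),
        "r_squared": fit.r_squared,
        "b2_unreliable": fit.b2_unreliable,
    }


def _cluster_summary(res: cl.ClusterResult) -> dict:
    out = {
        "sizes": dict(res.sizes),
        "centers": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in res.centers.items()
        },
    }
    if res.ranges is not None:
        out["ranges"] = {k: list(v) for k, v in res.ranges.items()}
    return out


def _lda_summary(model: da.DiscriminantModel) -> dict:
    return {
        "constant": model.constant,
        "weights": model.weights.tolist(),
        "boundary": model.boundary,
        "wilks_lambda": model.wilks_lambda,
        "chi2": model.chi2,
        "df": model.df,
        "p_value": model.p_value,
        "centroids": list(model.centroids),
        "n_per_group": list(model.n_per_group),
        "group_names": list(model.group_names),
    }


def _classification_summary(rep: da.ClassificationReport) -> dict:
    out = {"n": rep.n, "counts": dict(rep.counts)}
    if rep.expected_label is not None:
        out["expected_label"] = rep.expected_label
        out["n_matching"] = rep.n_matching
        out["percent_matching"] = rep.percent_matching
    return out


def _training_report(model: da.DiscriminantModel, X_ref, X_cmp) -> dict:
    ref_name, cmp_name = model.group_names
    rep_ref = da.verify_holdout(model, X_ref, ref_name)
    rep_cmp = da.verify_holdout(model, X_cmp, cmp_name)
    total = rep_ref.n + rep_cmp.n
    correct = rep_ref.n_matching + rep_cmp.n_matching
    return {
        ref_name: _classification_summary(rep_ref),
        cmp_name: _classification_summary(rep_cmp),
        "percent_correct_overall": 100.0 * correct / total,
    }


def _coefficient_analysis(
    coef: str,
    fits_ctrl: pd.DataFrame,
    fits_pat: pd.DataFrame,
    ctrl_rows: pd.DataFrame,
    pat_rows: pd.DataFrame,
    config: AnalysisConfig,
) -> dict:
    """Cluster controls and patients on one coefficient, then discriminate.

    Training pair: control higher cluster (reference) vs patient lower
    cluster (comparison); hold-outs are the two remaining clusters.
    """
    v_ctrl = fits_ctrl[coef].to_numpy(float)
    v_pat = fits_pat[coef].to_numpy(float)
    ctrl_clusters = cl.two_means_1d(v_ctrl)
    pat_clusters = cl.two_means_1d(v_pat)

    train_ref = v_ctrl[ctrl_clusters.labels == "higher"]
    train_cmp = v_pat[pat_clusters.labels == "lower"]
    hold_ctrl_lower = v_ctrl[ctrl_clusters.labels == "lower"]
    hold_pat_higher = v_pat[pat_clusters.labels == "higher"]

    model = da.fit_lda(
        train_ref[:, None],
        train_cmp[:, None],
        group_names=("healthy-like", "impaired"),
        boundary=config.boundary,
    )
    cutoff = da.threshold_from_function(
        model.constant, float(model.weights[0]), model.boundary
    )
    out = {
        "control_clusters": _cluster_summary(ctrl_clusters),
        "patient_clusters": _cluster_summary(pat_clusters),
        "lda": _lda_summary(model),
        "cutoff": cutoff,
        "training_classification": _training_report(
            model, train_ref[:, None], train_cmp[:, None]
        ),
        "holdout": {},
        "averaged_fits": {},
    }
    if len(hold_ctrl_lower):
        out["holdout"]["control_lower"] = _classification_summary(
            da.verify_holdout(model, hold_ctrl_lower[:, None], "healthy-like")
        )
    if len(hold_pat_higher):
        out["holdout"]["patient_higher"] = _classification_summary(
            da.verify_holdout(model, hold_pat_higher[:, None], "healthy-like")
        )
    # averaged learning curves of the four clusters, from raw trial scores
    for name, rows, clusters, which in (
        ("control_higher", ctrl_rows, ctrl_clusters, "higher"),
        ("control_lower", ctrl_rows, ctrl_clusters, "lower"),
        ("patient_lower", pat_rows, pat_clusters, "lower"),
        ("patient_higher", pat_rows, pat_clusters, "higher"),
    ):
        subset = rows.iloc[clusters.labels == which]
        if len(subset) >= 1:
            out["averaged_fits"][name] = _fit_summary(
                fit_averaged_curve(subset, config.max_score)
            )
    return out


def _trials_lda(ctrl_rows, pat_rows, config) -> dict:
    """Whole-group LDA on raw trials 1-5."""
    Xc = ctrl_rows[TRIAL_COLS].to_numpy(float)
    Xp = pat_rows[TRIAL_COLS].to_numpy(float)
    model = da.fit_lda(
        Xc, Xp, group_names=("healthy-like", "impaired"), boundary=config.boundary
    )
    return {
        "lda": _lda_summary(model),
        "training_classification": _training_report(model, Xc, Xp),
        "per_trial_t_tests": [
            {"trial": i + 1, "t": t, "p": p}
            for i, (t, p) in enumerate(da.compare_group_means(Xc, Xp))
        ],
    }


def _ward_cluster_lda(ctrl_rows, pat_rows, config) -> dict:
    """Ward clusters of trials 1-5, then LDA on control-higher vs patient-lower."""
    Xc = ctrl_rows[TRIAL_COLS].to_numpy(float)
    Xp = pat_rows[TRIAL_COLS].to_numpy(float)
    wc = cl.ward_trials(Xc, standardize=config.standardize_trials)
    wp = cl.ward_trials(Xp, standardize=config.standardize_trials)
    train_ref = Xc[wc.labels == "higher"]
    train_cmp = Xp[wp.labels == "lower"]
    out = {
        "control_clusters": _cluster_summary(wc),
        "patient_clusters": _cluster_summary(wp),
    }
    p = len(TRIAL_COLS)
    if len(train_ref) < p + 2 or len(train_cmp) < p + 2:
        out["skipped"] = "training clusters too small for 5-predictor LDA"
        return out
    try:
        model = da.fit_lda(
            train_ref, train_cmp,
            group_names=("healthy-like", "impaired"),
            boundary=config.boundary,
        )
    except CvltCurveError as exc:
        out["skipped"] = f"LDA failed: {exc}"
        return out
    out["lda"] = _lda_summary(model)
    out["training_classification"] = _training_report(model, train_ref, train_cmp)
    hold = {}
    lo_c = Xc[wc.labels == "lower"]
    hi_p = Xp[wp.labels == "higher"]
    if len(lo_c):
        hold["control_lower"] = _classification_summary(
            da.verify_holdout(model, lo_c, "healthy-like")
        )
    if len(hi_p):
        hold["patient_higher"] = _classification_summary(
            da.verify_holdout(model, hi_p, "healthy-like")
        )
    out["holdout"] = hold
    for name, rows, res, which in (
        ("control_lower", ctrl_rows, wc, "lower"),
        ("control_higher", ctrl_rows, wc, "higher"),
        ("patient_lower", pat_rows, wp, "lower"),
        ("patient_higher", pat_rows, wp, "higher"),
    ):
        subset = rows.iloc[res.labels == which]
        if len(subset):
            out.setdefault("averaged_fits", {})[name] = _fit_summary(
                fit_averaged_curve(subset, config.max_score)
            )
    return out


def run_full_analysis(cohort: pd.DataFrame, config: AnalysisConfig | None = None) -> dict:
    """Run the complete analysis; returns a JSON-serializable report."""
    config = config or AnalysisConfig()
    cohort = validate_cohort(cohort, max_score=config.max_score)

    report: dict = {
        "config": {**asdict(config), "coefficients": list(config.coefficients)},
        "n_subjects": int(len(cohort)),
        "strata": {},
        "skipped_strata": {},
    }
    for sex in sorted(cohort["sex"].unique()):
        stratum = cohort[cohort["sex"] == sex]
        ctrl = stratum[stratum["diagnosis"] == "control"]
        pat = stratum[stratum["diagnosis"] == "patient"]
        if len(ctrl) < config.min_stratum_size or len(pat) < config.min_stratum_size:
            reason = (
                f"needs >= {config.min_stratum_size} subjects per diagnosis, "
                f"got {len(ctrl)} controls / {len(pat)} patients"
            )
            log.warning("skipping stratum %s: %s", sex, reason)
            report["skipped_strata"][sex] = reason
            continue
        log.info("stratum %s: %d controls, %d patients", sex, len(ctrl), len(pat))

        fits = fit_all_subjects(stratum, config.max_score)
        merged = stratum.reset_index(drop=True).join(
            fits.set_index("subject_id"), on="subject_id", rsuffix="_fit"
        )
        n_failed = int((~merged["converged"]).sum())
        ok = merged[merged["converged"]]
        ctrl_ok = ok[ok["diagnosis"] == "control"]
        pat_ok = ok[ok["diagnosis"] == "patient"]

        entry: dict = {
            "n_control": int(len(ctrl)),
            "n_patient": int(len(pat)),
            "n_fit_failures": n_failed,
            "averaged_fits": {
                "control": _fit_summary(fit_averaged_curve(ctrl, config.max_score)),
                "patient": _fit_summary(fit_averaged_curve(pat, config.max_score)),
            },
            "coefficients": {},
        }
        for coef in config.coefficients:
            entry["coefficients"][coef] = _coefficient_analysis(
                coef, ctrl_ok, pat_ok, ctrl_ok, pat_ok, config
            )
        if config.include_trials_lda:
            entry["trials_lda"] = _trials_lda(ctrl, pat, config)
            entry["ward_clusters"] = _ward_cluster_lda(ctrl, pat, config)
        report["strata"][sex] = entry
    return report


def verify_report(report: dict, atol: float = 1e-9) -> list[str]:
    """Self-consistency pass: recompute cutoffs and percentages from the
    report's own stored models; returns a list of inconsistencies (empty
    when the report is internally consistent)."""
    problems = []
    for sex, stratum in report.get("strata", {}).items():
        for coef, block in stratum.get("coefficients", {}).items():
            lda = block["lda"]
            cut = da.threshold_from_function(
                lda["constant"], lda["weights"][0], lda["boundary"]
            )
            if abs(cut - block["cutoff"]) > atol:
                problems.append(f"{sex}/{coef}: stored cutoff {block['cutoff']} != {cut}")
            lo, hi = min(lda["centroids"]), max(lda["centroids"])
            if not (lo < lda["boundary"] < hi):
                problems.append(f"{sex}/{coef}: boundary outside centroids")
            for section in (block.get("holdout", {}) or {}).values():
                pct = 100.0 * section["n_matching"] / section["n"]
                if abs(pct - section["percent_matching"]) > 1e-6:
                    problems.append(f"{sex}/{coef}: holdout percentage inconsistent")
    return problems


def _round(x, nd):
    return "" if x is None else f"{x:.{nd}f}"


def render_report_text(report: dict) -> str:
    """Human-readable rendering: coefficients to 2 decimals, Wilks' lambda
    and chi-square to 3, percentages to 1."""
    lines = []
    add = lines.append
    add(f"Cohort: {report['n_subjects']} subjects")
    for sex, stratum in report.get("strata", {}).items():
        add("")
        add(f"=== Stratum {sex}: {stratum['n_control']} controls, "
            f"{stratum['n_patient']} patients "
            f"({stratum['n_fit_failures']} fit failures) ===")
        for grp in ("control", "patient"):
            f = stratum["averaged_fits"][grp]
            if f.get("converged"):
                add(f"  averaged curve [{grp}]: "
                    f"B2={f['B2']:.2f} B3={f['B3']:.2f} B4={f['B4']:.2f} "
                    f"R^2={f['r_squared']:.4f}")
        for coef, block in stratum.get("coefficients", {}).items():
            lda = block["lda"]
            sizes_c = block["control_clusters"]["sizes"]
            sizes_p = block["patient_clusters"]["sizes"]
            add(f"  -- {coef} --")
            add(f"    clusters: controls lower/higher {sizes_c['lower']}/{sizes_c['higher']}, "
                f"patients lower/higher {sizes_p['lower']}/{sizes_p['higher']}")
            add(f"    discriminant: y = {lda['constant']:.3f} + "
                f"{lda['weights'][0]:.3f} * {coef}; boundary Y_b = {lda['boundary']:.3f}")
            add(f"    Wilks' lambda = {lda['wilks_lambda']:.3f}, "
                f"chi2 = {lda['chi2']:.3f} (df={lda['df']}), p = {lda['p_value']:.3g}")
            add(f"    impairment cutoff: {coef} < {block['cutoff']:.2f}")
            tc = block["training_classification"]
            add(f"    training correct: {tc['percent_correct_overall']:.1f}%")
            for name, sec in (block.get("holdout") or {}).items():
                add(f"    holdout {name}: {sec['percent_matching']:.1f}% healthy-like "
                    f"({sec['n_matching']}/{sec['n']})")
    for sex, reason in report.get("skipped_strata", {}).items():
        add(f"Stratum {sex} skipped: {reason}")
    return "\n".join(lines) + "\n"


def write_report(path, report: dict) -> None:
    """Serialize the report as JSON; a ``.txt`` sibling gets the rendering."""
    path = Path(path)
    problems = verify_report(report)
    if problems:
        raise CvltCurveError("report failed self-verification: " + "; ".join(problems))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    with open(path.with_suffix(".txt"), "w", encoding="utf-8") as fh:
        fh.write(render_report_text(report))
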