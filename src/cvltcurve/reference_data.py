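"""Published group-level results from a CVLT-II study of memory in MS.

The clinical study this package's methods operationalize reported (a)
per-trial mean recall for whole groups and for Ward clusters of the five
trial scores, (b) learning-curve coefficients fitted to those averaged
curves, (c) univariate discriminant functions on B3 / B4 with their
boundary values and Wilks'-lambda tests, and (d) the resulting clinical
impairment cutoffs. Individual-level data were never deposited, so these
group-level summaries are the only public anchor: they serve as worked
examples, as regression fixtures, and as the inputs the acceptance checks
refit from scratch.

Keys are descriptive: ``healthy``/``ms`` x ``all``/``male``/``female``,
with ``_lower``/``_higher`` suffixes for the memory-functioning clusters
obtained from Ward clustering of trials 1-5.
"""

from __future__ import annotations

__all__ = [
    "GROUP_TRIAL_MEANS",
    "PUBLISHED_CURVE_FITS",
    "UNIVARIATE_DISCRIMINANTS",
    "PUBLISHED_CUTOFFS",
    "WILKS_TESTS",
    "TRIALS_DISCRIMINANTS",
    "SUBGROUP_CURVE_PARAMS",
]

#: Mean words recalled on trials 1-5 (group averages, 2 decimals).
GROUP_TRIAL_MEANS: dict[str, tuple[float, ...]] = {
    "healthy_all": (7.26, 10.67, 12.22, 13.09, 13.76),
    "ms_all": (6.15, 9.16, 10.46, 11.32, 11.66),
    "healthy_male": (5.90, 8.75, 10.75, 11.55, 12.50),
    "healthy_female": (7.60, 11.17, 12.60, 13.49, 14.08),
    "ms_male": (5.65, 8.15, 9.30, 10.17, 10.42),
    "ms_female": (6.33, 9.53, 10.89, 11.74, 12.12),
    # Ward clusters of trials 1-5 within sex x diagnosis:
    "healthy_male_lower": (4.44, 7.44, 9.78, 10.33, 11.00),
    "healthy_male_higher": (6.82, 9.82, 11.27, 12.36, 13.55),
    "ms_male_lower": (4.78, 6.41, 7.20, 7.63, 8.02),
    "ms_male_higher": (6.40, 9.66, 11.13, 12.38, 12.51),
    "healthy_female_lower": (6.82, 9.68, 10.92, 12.24, 13.24),
    "healthy_female_higher": (8.35, 12.58, 14.20, 14.68, 14.88),
    "ms_female_lower": (5.32, 7.73, 8.75, 9.68, 10.29),
    "ms_female_higher": (7.35, 11.34, 13.02, 13.81, 13.95),
}

#: Coefficients reported for fits to the averaged curves above.
#: r_squared is None where it was not reported (the cluster curves).
PUBLISHED_CURVE_FITS: dict[str, dict] = {
    "healthy_all": {"B2": 0.65, "B3": 7.28, "B4": 14.17, "r_squared": 0.9987},
    "healthy_female": {"B2": 0.70, "B3": 7.63, "B4": 14.38, "r_squared": 0.9982},
    "healthy_male": {"B2": 0.47, "B3": 5.90, "B4": 13.58, "r_squared": 0.9978},
    "ms_all": {"B2": 0.70, "B3": 6.16, "B4": 12.01, "r_squared": 0.9992},
    "ms_female": {"B2": 0.72, "B3": 6.35, "B4": 12.44, "r_squared": 0.9993},
    "ms_male": {"B2": 0.64, "B3": 5.66, "B4": 10.86, "r_squared": 0.9987},
    "healthy_male_lower": {"B2": None, "B3": 4.39, "B4": 11.69, "r_squared": None},
    "healthy_male_higher": {"B2": None, "B3": 6.90, "B4": 15.0, "r_squared": None},
    "ms_male_lower": {"B2": None, "B3": 4.80, "B4": 8.29, "r_squared": None},
    "ms_male_higher": {"B2": None, "B3": 6.40, "B4": 13.10, "r_squared": None},
    "healthy_female_lower": {"B2": None, "B3": 6.90, "B4": 14.92, "r_squared": None},
    "healthy_female_higher": {"B2": None, "B3": 8.34, "B4": 15.01, "r_squared": None},
    "ms_female_lower": {"B2": None, "B3": 5.36, "B4": 10.99, "r_squared": None},
    "ms_female_higher": {"B2": None, "B3": 7.34, "B4": 14.22, "r_squared": None},
}

#: Published univariate discriminant functions y = constant + weight * B,
#: with their boundary values Y_b (scores >= Y_b classify as unimpaired).
#: Training pairs were the healthy higher-functioning cluster vs the MS
#: lower-functioning cluster of the same coefficient and sex.
UNIVARIATE_DISCRIMINANTS: dict[str, dict[str, float]] = {
    "male_b3": {"constant": -4.518, "weight": 0.937, "boundary": 0.958},
    "male_b4": {"constant": -4.923, "weight": 0.466, "boundary": 0.681},
    "female_b3": {"constant": -4.923, "weight": 0.827, "boundary": 0.672},
    "female_b4": {"constant": -8.399, "weight": 0.679, "boundary": 0.285},
}

#: Clinical impairment cutoffs on the coefficient scale (words): a patient
#: below the cutoff classifies as impaired on that memory component.
PUBLISHED_CUTOFFS: dict[str, float] = {
    "male_b3": 5.84,
    "male_b4": 12.03,
    "female_b3": 6.76,
    "female_b4": 12.79,
}

#: Every reported Wilks' lambda with its group sizes, predictor count and
#: the chi-square statistic printed alongside it.
WILKS_TESTS: list[dict] = [
    {"name": "trials_all", "wilks_lambda": 0.894, "n_a": 98, "n_b": 365, "p": 5, "chi2": 51.25},
    {"name": "trials_male", "wilks_lambda": 0.893, "n_a": 20, "n_b": 99, "p": 5, "chi2": 12.996},
    {"name": "trials_female", "wilks_lambda": 0.878, "n_a": 78, "n_b": 266, "p": 5, "chi2": 44.064},
    {"name": "trials_male_clusters", "wilks_lambda": 0.421, "n_a": 11, "n_b": 46, "p": 5, "chi2": 45.4},
    {"name": "trials_female_clusters", "wilks_lambda": 0.282, "n_a": 40, "n_b": 133, "p": 5, "chi2": 213.0},
    {"name": "male_b3", "wilks_lambda": 0.406, "n_a": 11, "n_b": 48, "p": 1, "chi2": 50.958},
    {"name": "male_b4", "wilks_lambda": 0.534, "n_a": 15, "n_b": 59, "p": 1, "chi2": 44.820},
    {"name": "female_b3", "wilks_lambda": 0.372, "n_a": 56, "n_b": 152, "p": 1, "chi2": 202.964},
    {"name": "female_b4", "wilks_lambda": 0.301, "n_a": 75, "n_b": 109, "p": 1, "chi2": 217.890},
]

#: Published five-predictor discriminant functions on raw trials 1-5.
#: These cannot be re-derived without the individual-level data; they are
#: kept as fixtures for classification and inversion demos only.
TRIALS_DISCRIMINANTS: dict[str, dict] = {
    "all": {
        "constant": -4.774,
        "weights": (0.1564, -0.040, 0.047, -0.04906, 0.349),
        "boundary": 0.420,
    },
    "male": {
        "constant": -2.666,
        "weights": (-0.104, -0.245, 0.295, -0.306, 0.523),
        "boundary": 0.305,
    },
    "female": {
        "constant": -5.378,
        "weights": (0.20, 0.245, -0.018, 0.011, 0.319),
        "boundary": 0.242,
    },
    "male_clusters": {
        "constant": -5.123,
        "weights": (-0.16, 0.18, 0.186, 0.115, 0.287),
        "boundary": 1.459,
    },
    "female_clusters": {
        "constant": -7.326,
        "weights": (0.121, 0.191, 0.295, 0.114, 0.063),
        "boundary": 1.881,
    },
}

#: Coefficients of the averaged curves of the B3-based two-means clusters
#: (per sex x diagnosis x lower/higher). These anchor the synthetic-cohort
#: generator's subgroup means: the latent lower/higher memory-functioning
#: mixture each cohort cell is built from.
SUBGROUP_CURVE_PARAMS: dict[tuple[str, str, str], dict[str, float]] = {
    ("M", "control", "lower"): {"B2": 0.4407, "B3": 3.91, "B4": 13.72},
    ("M", "control", "higher"): {"B2": 0.5274, "B3": 7.50, "B4": 13.46},
    ("M", "patient", "lower"): {"B2": 0.6505, "B3": 4.26, "B4": 9.81},
    ("M", "patient", "higher"): {"B2": 0.6179, "B3": 6.97, "B4": 11.85},
    ("F", "control", "lower"): {"B2": 0.7231, "B3": 5.27, "B4": 14.28},
    ("F", "control", "higher"): {"B2": 0.6877, "B3": 8.56, "B4": 14.43},
    ("F", "patient", "lower"): {"B2": 0.6286, "B3": 5.06, "B4": 11.62},
    ("F", "patient", "higher"): {"B2": 0.8507, "B3": 8.08, "B4": 13.63},
}
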