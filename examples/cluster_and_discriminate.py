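"""Cluster fitted B3 values and train a discriminant function.

The core procedure on one stratum (males): fit every subject's curve, split
controls and patients into lower/higher clusters by exact 1-D two-means on
B3, train Fisher LDA on the control-higher vs patient-lower clusters, and
invert the function at its boundary into an impairment cutoff.
"""

import numpy as np

from cvltcurve import fit_lda, generate_cohort, threshold_from_function, two_means_1d
from cvltcurve.pipeline import fit_all_subjects

cohort = generate_cohort(n_per_cell=80, seed=11)
males = cohort[cohort.sex == "M"]
fits = males.merge(fit_all_subjects(males), on="subject_id")
fits = fits[fits.converged]

ctrl = fits[fits.diagnosis == "control"]["B3"].to_numpy()
pat = fits[fits.diagnosis == "patient"]["B3"].to_numpy()
kc, kp = two_means_1d(ctrl), two_means_1d(pat)
print(f"controls: lower/higher {kc.sizes['lower']}/{kc.sizes['higher']}, "
      f"ranges {kc.ranges['lower']} | {kc.ranges['higher']}")
print(f"patients: lower/higher {kp.sizes['lower']}/{kp.sizes['higher']}")

train_ref = ctrl[kc.labels == "higher"][:, None]
train_cmp = pat[kp.labels == "lower"][:, None]
m = fit_lda(train_ref, train_cmp, group_names=("healthy-like", "impaired"))
cutoff = threshold_from_function(m.constant, float(m.weights[0]), m.boundary)
print(f"\ndiscriminant: y = {m.constant:.3f} + {m.weights[0]:.3f}*B3, "
      f"Y_b = {m.boundary:.3f}")
print(f"Wilks' lambda = {m.wilks_lambda:.3f}, chi2 = {m.chi2:.3f}, "
      f"p = {m.p_value:.2e}")
print(f"male B3 impairment cutoff: {cutoff:.2f} words")
print(
    "\nThe cutoff sits between the control-higher and patient-lower cluster"
    "\nmeans; a small lambda / large chi-square says the clusters separate."
)
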