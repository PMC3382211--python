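"""Derive clinical impairment cutoffs from discriminant functions.

A univariate discriminant function y = C0 + C1*B with boundary Y_b
classifies a patient as unimpaired when y >= Y_b. Solving y = Y_b for the
coefficient gives a cutoff on the B3/B4 scale directly: e.g. a male MS
patient with B3 below the male-B3 cutoff shows impaired readiness to learn.
"""

from cvltcurve import classify, threshold_from_function
from cvltcurve.discriminant import DiscriminantModel
import numpy as np

from cvltcurve.reference_data import UNIVARIATE_DISCRIMINANTS

for key, fn in UNIVARIATE_DISCRIMINANTS.items():
    cutoff = threshold_from_function(fn["constant"], fn["weight"], fn["boundary"])
    sex, coef = key.split("_")
    print(
        f"{sex:<7} {coef.upper()}: y = {fn['constant']:+.3f} "
        f"{fn['weight']:+.3f}*{coef.upper()}, Y_b = {fn['boundary']:.3f} "
        f"->  impaired if {coef.upper()} < {cutoff:.2f} words"
    )

fn = UNIVARIATE_DISCRIMINANTS["male_b3"]
model = DiscriminantModel(
    constant=fn["constant"], weights=np.array([fn["weight"]]),
    boundary=fn["boundary"], wilks_lambda=0.406, chi2=50.958, df=1,
    p_value=1e-12, centroids=(1.9, -1.6), n_per_group=(11, 48),
    group_names=("unimpaired", "impaired"),
)
label, score = classify(model, [5.64])
print(f"\nExample: male patient with B3 = 5.64 scores y = {score:.3f} "
      f"< Y_b = {fn['boundary']}, classified {label}.")
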