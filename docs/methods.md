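# Methods

## Model

Free recall of a 16-word list over five trials is treated as the step
response of a first-order system: with time constant τ = 1/B2, initial
level y₀ = B3 and steady state y_ss = B4, the solution
y = (y₀ − y_ss)e^(−at) + y_ss becomes, on the trial index X starting at 1,

    Y(X) = B3·exp(−B2·(X−1)) + B4·(1 − exp(−B2·(X−1))).

Using X − 1 makes B3 the exact trial-1 prediction, so B3 tracks attention
span and short-term encoding while B4 tracks the long-term consolidation
ceiling. B2 is reported but treated as poorly identified from five trials:
its construct validity is weak, and when B3 ≈ B4 the curve is flat and B2
is unidentifiable — the fit then flags `b2_unreliable` whenever the B2
standard error exceeds the estimate rather than failing.

The conventional "learning slope" (OLS slope of recall on trial number) and
Y_max − Y_1 are provided for comparison; both are ceiling-sensitive, which
is the motivation for the model-based summaries.

## Estimation

`fit_learning_curve` minimizes Σ(Y − model)² with `scipy.optimize.curve_fit`
(trust-region reflective under box bounds). Choices:

* **Initialization** B3₀ = Y(1), B4₀ = Y(last), B2₀ = 0.5; a restart grid
  B2₀ ∈ {0.1, 0.5, 1, 2} is always evaluated and the lowest-SSE success
  kept, which removes start dependence on well-conditioned data (verified
  to 1e-8 in tests).
* **Bounds** B2 ∈ (1e-4, 10], B3 ∈ [0, 16], B4 ∈ [0, 20]. The B4 headroom
  above the 16-word ceiling avoids censoring near-ceiling learners; the
  published record itself contains an unbounded-fit blow-up (a flat cluster
  curve with B2 = 2.08 ± 3.62, R² = 0.73), which the flat-curve flag covers.
* **Uncertainty** Asymptotic standard errors from the Gauss–Newton
  curvature at the optimum, scaled by residual variance with n − 3 degrees
  of freedom (curve_fit's covariance); cross-checked in tests against a
  finite-difference Jacobian oracle to 1e-4 relative.
* **Fit quality** R² = 1 − SS_res/SS_tot, SS_tot about the mean of the
  fitted points. A failed fit returns `converged=False` with diagnostics,
  never a fabricated estimate.
* Real-valued inputs are accepted (averaged group curves are means);
  integer range checks apply at the cohort-table layer only.

Coefficient differences between independent fits use a Wald z statistic
(b_a − b_b)/√(se_a² + se_b²) against the normal reference. A t reference
would need degrees of freedom that the asymptotic theory does not supply
for two separate nonlinear fits; the intended use is direction-of-effect
and significance-level statements, not exact p values.

## Clustering

Two-means on a single coefficient is solved **exactly**: optimal 1-D
2-clusters are contiguous in sorted order, so the n − 1 contiguous splits
are scanned and the global within-cluster-SSE minimum taken. This is
deterministic (no seeds, no Lloyd iterations; ties broken toward the more
balanced split, then the lower split index) and yields the non-overlapping
lower/higher ranges the procedure relies on. Ward clustering of the five
raw trial scores uses `scipy.cluster.hierarchy` (Ward linkage, tree cut at
two clusters), on raw scores by default since all five variables share
units; a standardization switch exists. Cluster naming is by mean of the
clustered variable ("higher" = larger mean); an exact tie raises rather
than guessing. Greedy agglomeration does not guarantee the globally optimal
2-partition on structureless data; tests verify optimality in the
two-component regime the procedure assumes.

## Discriminant analysis

Two-group Fisher LDA with the display conventions of the major statistics
packages: weights ∝ S_pooled⁻¹(m_a − m_b) rescaled to unit pooled
within-group score variance (S_pooled uses divisor N − g), constant set so
the size-weighted grand mean score is zero, sign set so the reference
(healthy) group scores higher. The boundary Y_b is the unweighted midpoint
of the two group centroids — the inversion of published functions at their
boundaries reproduces all four published clinical cutoffs, which validates
the convention indirectly; a size-weighted variant is available by config.
Scores ≥ Y_b classify as unimpaired (boundary inclusive). Equal priors are
implied by the single fixed boundary; no stepwise selection anywhere.
Separation is tested with Wilks' Λ = |W|/|T| and Bartlett's
χ² = −(N − 1 − (p + g)/2)·ln Λ on p(g − 1) df; this formula reconciles all
nine published (Λ, χ²) pairs within 0.5. The five-predictor trial-score
functions from the published record are shipped as fixtures only — they
cannot be re-derived without individual-level data.

## Synthetic cohorts

Each sex × diagnosis cell mixes a lower and a higher memory-functioning
subgroup. Subgroup coefficient means are the published averaged-curve
coefficients of the B3-based clusters (e.g. MS-male lower B3 = 4.26,
B4 = 9.81; healthy-male higher B3 = 7.50, B4 = 13.46). Lower-subgroup
weights: 0.5 in patient cells and 0.45 (M) / 0.30 (F) in control cells,
matching the reported cluster proportions. Coefficients are drawn from
normals truncated to the fit bounds by resampling (no point mass at the
bounds) with between-subject SD 1.0 word for B3/B4 — the record reports
only standard errors of averaged fits, so population dispersion is a
package choice — and SD 0.15 for B2 (a 1-word SD is meaningless for a
positive rate with mean ≈ 0.65). Observed counts are the model curve plus
Gaussian noise (SD 1.0/trial), rounded and clipped to [0, 16]; a
binomial(16, μ/16) alternative produces integer counts without additive
noise. Rounding can be disabled for noiseless recovery checks.

What the generator does **not** emulate: practice/fatigue dynamics across
trials beyond the exponential form, item-level effects (serial position,
semantic clustering), correlation between B2/B3/B4 within subject, and any
non-Gaussian heaviness in real coefficient dispersion. Passing end-to-end
tests therefore demonstrate the pipeline's correctness and its behavior
under the calibrated mixture — not clinical performance on real cohorts.

A quantitative consequence, measured here: with 1-word between-subject SD
and 1-word trial noise, the per-subject B3 estimate carries ≈1 word of
estimation error, so total B3 dispersion is ≈√2 against subgroup gaps of
2.7–3.6 words. Two-means on fitted B3 then recovers ≈85–88% of latent
subgroup labels (≈93% when clustering the true B3) — informative but below
a 90% bar at the default calibration, while the trained discriminants still
classify ≥95% (typically 99–100%) of their reference clusters. This is an
intrinsic overlap property of the calibrated mixture, not an implementation
artifact.

## Pipeline

Per sex stratum (strata with fewer than 6 subjects in either diagnosis are
skipped with a logged reason): individual fits (non-convergent subjects are
excluded from coefficient analyses but kept in raw-trials analyses, with
counts reported); two-means on B3 and B4; LDA trained on control-higher vs
patient-lower clusters — the selection rule the study procedure fixes —
with hold-out verification on control-lower and patient-higher; the
raw-trials comparisons (whole-group LDA, Ward-cluster LDA, per-trial pooled
t-tests); averaged-curve fits per group and cluster. The report is
JSON-serializable and passes a self-verification that recomputes cutoffs
and percentages from its own stored models before writing; text rendering
rounds coefficients to 2 decimals, Λ/χ² to 3, percentages to 1.

Identical cohort + config produce byte-identical reports; all randomness
lives in the generator and is seed-controlled.

## Problem sizes

Default test and acceptance runs use 5-point averaged-curve fits
(deterministic), oracle sweeps up to n = 200 for the exact 1-D clustering,
exhaustive bipartitions up to n = 6 for Ward, and seeded synthetic cohorts
of 200 subjects per sex × diagnosis cell (800 total) for the end-to-end
checks — large enough that subgroup-recovery rates are estimated to ~±2
percentage points.

## Known limitations

* B4 is an extrapolation beyond trial 5; with slow learners (small B2) it
  is upward-biased and high-variance (RMSE ≈ 3 words at default noise).
* B2 is reported but should not be interpreted in isolation.
* The Wald coefficient comparison is asymptotic; with 2 residual df per
  averaged-curve fit its exact p-values are approximate by construction.
* Published five-predictor trial functions are fixtures; only univariate
  B3/B4 discriminants are re-derivable and re-derived.
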