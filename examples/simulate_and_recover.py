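"""Generate a synthetic cohort and check coefficient recovery.

The generator draws each subject's true (B2, B3, B4) from a lower/higher
memory-functioning mixture calibrated to the published cluster curves, then
adds per-trial noise and rounds to integer word counts. Refitting every
subject's curve quantifies how well the coefficients survive five noisy
integer observations.
"""

from cvltcurve import generate_cohort, recovery_report

cohort = generate_cohort(n_per_cell=100, seed=42)
print(f"cohort: {len(cohort)} subjects, "
      f"{(cohort.latent_subgroup == 'lower').sum()} in lower subgroups")
print(cohort.head(3).to_string(index=False))

rep = recovery_report(cohort)
print(f"\nconvergence: {rep['n_converged']}/{rep['n_subjects']} "
      f"({100 * rep['convergence_rate']:.1f}%)")
for coef, stats in rep["coefficients"].items():
    print(f"  {coef}: bias {stats['bias']:+.3f}, RMSE {stats['rmse']:.3f}")
print(
    "\nB3 comes back nearly unbiased with ~1-word RMSE at 1-word trial noise:"
    "\nit is anchored by trial 1. B4 extrapolates past trial 5, so it drifts"
    "\nupward when the curve has not flattened yet, and B2 (the rate) is the"
    "\nleast identifiable from five trials."
)
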