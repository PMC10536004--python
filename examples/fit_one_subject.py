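"""Fit one noisy subject's EGC data and compare estimates with the truth.

Generates a single virtual subject (20% proportional measurement error,
30% inter-subject spread), fits the five estimable transfer coefficients
by weighted least squares, and prints estimate, truth, and fractional
standard deviation (FSD = SE/estimate) per coefficient.
"""

from teacat import build_final_structure, default_truth, fit_series, generate_cohort

structure = build_final_structure()
truth = default_truth()
cohort = generate_cohort(truth, n_subjects=1, seed=42)
series = [s for s in cohort.series if s.catechin == "EGC"][0]

fit = fit_series(series, structure)
realized = cohort.realized_params[(series.subject_id, "EGC")]

print(f"subject {series.subject_id}, catechin EGC "
      f"(converged={fit.converged}, weighted SSR={fit.weighted_ssr:.2f})")
print(f"{'transfer':34s} {'estimate':>9s} {'truth':>9s} {'FSD':>6s}")
for i, e in enumerate(fit.param_order):
    print(f"{e[0] + ' -> ' + e[1]:34s} {fit.params.values[e]:9.4f} "
          f"{realized.values[e]:9.4f} {fit.fsd[i]:6.2f}")
print(f"max |parameter correlation| = {fit.max_correlation:.3f}")
print(f"identifiability flags       = {fit.flags}")
print()
print("FSD < 0.5 and |corr| < 0.8 are the acceptance criteria for a")
print("well-identified fit; the weighted SSR is on the order of the number")
print("of observations when the proportional-error weights match the noise.")
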