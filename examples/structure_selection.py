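"""Is the extravascular compartment worth its parameters?

Regenerates noise-free data from the 7-compartment model and fits both
the 6-compartment starting structure (no extravascular pool) and the
full model.  Added complexity is flagged as justified only when it
improves both the weighted SSR and the worst fractional standard
deviation — the same double criterion used during model development.
"""

from teacat import (
    build_final_structure,
    build_variant_structure,
    compare_structures,
    default_truth,
    generate_cohort,
)
from teacat.synthetic import SyntheticTruth

truth = default_truth()
clean = SyntheticTruth(truth.parameter_sets, inter_subject_cv=0.0,
                       measurement_cv=0.0, seed=1)
series = [s for s in generate_cohort(clean, n_subjects=1).series
          if s.catechin == "EGC"][0]

report = compare_structures(
    [build_variant_structure("no_extravascular"), build_final_structure()],
    series,
    labels=["six_compartment", "seven_compartment"],
)
print(report[["label", "n_params", "weighted_ssr", "max_fsd", "justified"]]
      .to_string(index=False))
print()
print("The 6-compartment model cannot reproduce the biphasic plasma decay of")
print("data that contain tissue exchange, so the extravascular pool improves")
print("both criteria and earns its place — matching the development history.")
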