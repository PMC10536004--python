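"""Forward-simulate an EGCG bolus through the 7-compartment model.

Builds the final whole-body structure, loads the EGCG truth parameters,
and prints the fraction of the ingested dose in each pool over the first
12 h.  Every row sums to 1: the dose is only ever redistributed, never
created or destroyed.
"""

import numpy as np

from teacat import build_final_structure, default_truth, simulate

structure = build_final_structure()
params = default_truth().parameter_sets["EGCG"]

times = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0]
traj = simulate(structure, params, times)

cols = ["upper_GI", "small_intestine", "large_intestine", "liver", "plasma",
        "kidneys", "extravascular", "feces", "urine", "extravascular_loss"]
print("time_h  " + "  ".join(f"{c[:9]:>9s}" for c in cols) + "     total")
for i, t in enumerate(times):
    print(f"{t:5.1f}  " + "  ".join(f"{traj[c][i]:9.5f}" for c in cols)
          + f"  {traj.states[i].sum():9.6f}")

print()
print("The plasma column is what a blood draw sees (at most a few percent of")
print("the dose); by 24 h two thirds of the dose has reached feces (the fixed")
print("1:2 absorption split) and the rest has left through urine or tissues.")
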