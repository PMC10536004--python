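"""Calibrate the shipped synthetic truth fixture and write it to package data.

Run once from the repository root:

    python scripts/calibrate_truth.py

Plasma-side coefficients are solved in closed form from the target
contrasts; the remaining degree of freedom (ECG's kidneys→urine drain)
is solved numerically so the 24-h cumulative urinary recovery contrast
holds at the study's actual collection horizon.  The result is stored
as data (src/teacat/data/default_truth.yaml) and never recomputed at
import time.

Targets encoded here:
  * non-gallated / gallated mean plasma→kidneys coefficient = 150
  * non-gallated / gallated mean cumulative 24-h urinary fraction = 150
  * trihydroxylated / dihydroxylated mean FCR = 1.48
  * non-gallated / gallated mean FCR = 1.43
  * FCR ordering EGC > EGCG ≈ EC > ECG (residence time reversed)
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from teacat.fitting import default_initialization
from teacat.kinetics import fcr, residence_time_plasma
from teacat.model import (
    CATECHINS,
    URINE_INTERVAL_ENDS,
    build_final_structure,
    observe,
    simulate,
)
from teacat.synthetic import SyntheticTruth, truth_to_dict

TRI_DI_FCR_RATIO = 1.48
NONGAL_GAL_FCR_RATIO = 1.43
KIDNEY_UPTAKE_RATIO = 150.0
URINE_24H_RATIO = 150.0

E = {
    "gi": ("upper_GI", "small_intestine"),
    "abs": ("small_intestine", "liver"),
    "lp": ("liver", "plasma"),
    "pk": ("plasma", "kidneys"),
    "pe": ("plasma", "extravascular"),
    "ep": ("extravascular", "plasma"),
    "el": ("extravascular", "extravascular_loss"),
    "ku": ("kidneys", "urine"),
}


def build_truth_params():
    structure = build_final_structure()
    template = default_initialization(structure)

    # relative FCR (h^-1 scale factors): ECG = 1, EC = 2; solve EGCG, EGC from
    #   (EGC + EGCG) / (ECG + EC) = 1.48   (tri / di)
    #   (EGC + EC) / (EGCG + ECG) = 1.43   (non-gallated / gallated)
    # An exact EGCG = EC would force both ratios equal, so the 1.48 / 1.43
    # split implies a small (~3%) EGCG-EC gap; the reported "EGCG = EC"
    # is a Tukey non-difference, not an identity.
    ec_rel, ecg_rel = 2.0, 1.0
    egcg_rel = (
        (TRI_DI_FCR_RATIO - NONGAL_GAL_FCR_RATIO) * ecg_rel
        + (TRI_DI_FCR_RATIO + 1.0) * ec_rel
    ) / (1.0 + NONGAL_GAL_FCR_RATIO)
    egc_rel = TRI_DI_FCR_RATIO * (ecg_rel + ec_rel) - egcg_rel
    rel = {"EGC": egc_rel, "EGCG": egcg_rel, "EC": ec_rel, "ECG": ecg_rel}
    assert rel["EGC"] > rel["EGCG"] > rel["EC"] > rel["ECG"]

    scale = 0.8  # FCR_h of ECG; sets plasma residence times between ~0.5 and 1.25 h
    fcr_h = {c: rel[c] * scale for c in CATECHINS}

    # plasma side: FCR_h = k_pk + k_pe * (1 - r), r = k_ep / (k_ep + k_el).
    # The extravascular return/loss pair is held at the default fixed values
    # (0.6 / 0.6, r = 0.5) shared by all catechins — it is not estimable from
    # plasma + urine sampling, so truth and fit agree by construction — and
    # the tissue-uptake coefficient absorbs the whole FCR contrast.
    # Only the group means of the renal-uptake coefficient are constrained
    # (ratio 150); the within-group splits are design freedom spent on
    # identifiability — they keep every catechin's extravascular pathway
    # visible in plasma (k_pe well away from 0) and minimize how much 24-h
    # truncation the urinary-recovery contrast requires.
    k_pk = {"EGC": 1.2, "EC": 1.0, "EGCG": 0.011, "ECG": 1.1 / 150 * 2 - 0.011}
    r = 0.5
    k_pe = {c: (fcr_h[c] - k_pk[c]) / (1.0 - r) for c in CATECHINS}
    for c in CATECHINS:
        assert k_pe[c] > 0, (c, k_pe[c])

    # absorption side: upper-GI emptying is fixed (2.5 h⁻¹, shared); the
    # small-intestine and liver rates carry the reported orderings
    # (EC fastest / ECG slowest absorption; EGC > EC > EGCG ≈ ECG hepatic
    # efflux) and are spaced for a well-conditioned fit.
    k_abs = {"EGCG": 0.12, "EGC": 0.15, "EC": 0.20, "ECG": 0.08}
    k_lp = {"EGC": 1.8, "EC": 1.6, "EGCG": 1.2, "ECG": 1.1}
    # renal drains: fast for non-gallated; the shared gallated value is the
    # single remaining degree of freedom, solved so the urinary-recovery
    # contrast holds at the study's actual 24-h collection horizon.
    k_ku = {"EGC": 0.35, "EC": 0.45, "EGCG": np.nan, "ECG": np.nan}

    def params_for(c, ku_gal=None):
        ku = ku_gal if c in ("EGCG", "ECG") else k_ku[c]
        return template.with_values(
            {
                E["abs"]: k_abs[c],
                E["lp"]: k_lp[c],
                E["pk"]: k_pk[c],
                E["pe"]: k_pe[c],
                E["ku"]: ku,
            }
        ).resolve()

    def urine24(ps):
        grid = np.array([0.0, *URINE_INTERVAL_ENDS])
        traj = simulate(structure, ps, grid)
        _, urine = observe(traj, structure, [0.0], URINE_INTERVAL_ENDS)
        return urine[-1]

    u_ng = {c: urine24(params_for(c)) for c in ("EGC", "EC")}

    def ratio_gap(ku_gal):
        den = 0.5 * (urine24(params_for("EGCG", ku_gal)) + urine24(params_for("ECG", ku_gal)))
        return 0.5 * (u_ng["EGC"] + u_ng["EC"]) / den - URINE_24H_RATIO

    ku_gal = brentq(ratio_gap, 1e-3, 1.5, xtol=1e-12, rtol=1e-14)
    k_ku["EGCG"] = k_ku["ECG"] = ku_gal
    return structure, {c: params_for(c, ku_gal) for c in CATECHINS}


def main():
    structure, psets = build_truth_params()
    truth = SyntheticTruth(parameter_sets=psets)

    # report the calibration checks
    rts = {c: residence_time_plasma(structure, psets[c]) for c in CATECHINS}
    fcrs = {c: fcr(rts[c]) for c in CATECHINS}
    grid = np.array([0.0, *URINE_INTERVAL_ENDS])
    u24 = {}
    for c in CATECHINS:
        traj = simulate(structure, psets[c], grid)
        _, urine = observe(traj, structure, [0.0], URINE_INTERVAL_ENDS)
        u24[c] = urine[-1]
    kpk = {c: psets[c].values[E["pk"]] for c in CATECHINS}

    def mean(d, ks):
        return np.mean([d[k] for k in ks])

    print("FCR (per min):", {c: round(fcrs[c], 5) for c in CATECHINS})
    print("RT (h):       ", {c: round(rts[c], 4) for c in CATECHINS})
    print("urine 24 h:   ", {c: round(u24[c], 6) for c in CATECHINS})
    print("kidney-uptake ratio:", mean(kpk, ["EGC", "EC"]) / mean(kpk, ["EGCG", "ECG"]))
    print("urine-24h ratio:    ", mean(u24, ["EGC", "EC"]) / mean(u24, ["EGCG", "ECG"]))
    print("tri/di FCR ratio:   ", mean(fcrs, ["EGCG", "EGC"]) / mean(fcrs, ["ECG", "EC"]))
    print("nongal/gal FCR:     ", mean(fcrs, ["EGC", "EC"]) / mean(fcrs, ["EGCG", "ECG"]))

    out = Path(__file__).resolve().parents[1] / "src" / "teacat" / "data" / "default_truth.yaml"
    out.parent.mkdir(parents=True, exist_ok=True)
    doc = truth_to_dict(truth)
    header = (
        "# Calibrated per-catechin truth parameters for the synthetic cohort.\n"
        "# Produced by scripts/calibrate_truth.py; stored as data, not recomputed.\n"
        "# Coefficients are fractional transfer rates in h^-1 on the final\n"
        "# 7-compartment structure; the small_intestine->large_intestine value\n"
        "# is linked (2x absorption) and large_intestine->feces is fixed.\n"
    )
    with open(out, "w") as fh:
        fh.write(header)
        yaml.safe_dump(doc, fh, sort_keys=True)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
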