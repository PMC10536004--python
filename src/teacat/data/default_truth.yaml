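# Calibrated per-catechin truth parameters for the synthetic cohort.
# Produced by scripts/calibrate_truth.py; stored as data, not recomputed.
# Coefficients are fractional transfer rates in h^-1 on the final
# 7-compartment structure; the small_intestine->large_intestine value
# is linked (2x absorption) and large_intestine->feces is fixed.
coefficients_per_h:
  EC:
    extravascular->extravascular_loss: 0.6
    extravascular->plasma: 0.6
    kidneys->urine: 0.45
    large_intestine->feces: 0.5
    liver->plasma: 1.6
    plasma->extravascular: 1.2000000000000002
    plasma->kidneys: 1.0
    small_intestine->large_intestine: 0.4
    small_intestine->liver: 0.2
    upper_GI->small_intestine: 2.5
  ECG:
    extravascular->extravascular_loss: 0.6
    extravascular->plasma: 0.6
    kidneys->urine: 0.08043893993258927
    large_intestine->feces: 0.5
    liver->plasma: 1.1
    plasma->extravascular: 1.5926666666666667
    plasma->kidneys: 0.0036666666666666688
    small_intestine->large_intestine: 0.16
    small_intestine->liver: 0.08
    upper_GI->small_intestine: 2.5
  EGC:
    extravascular->extravascular_loss: 0.6
    extravascular->plasma: 0.6
    kidneys->urine: 0.35
    large_intestine->feces: 0.5
    liver->plasma: 1.8
    plasma->extravascular: 1.4052345679012337
    plasma->kidneys: 1.2
    small_intestine->large_intestine: 0.3
    small_intestine->liver: 0.15
    upper_GI->small_intestine: 2.5
  EGCG:
    extravascular->extravascular_loss: 0.6
    extravascular->plasma: 0.6
    kidneys->urine: 0.08043893993258927
    large_intestine->feces: 0.5
    liver->plasma: 1.2
    plasma->extravascular: 3.2767654320987663
    plasma->kidneys: 0.011
    small_intestine->large_intestine: 0.24
    small_intestine->liver: 0.12
    upper_GI->small_intestine: 2.5
doses_mg:
  EC: 39.0
  ECG: 28.0
  EGC: 87.0
  EGCG: 290.0
inter_subject_cv: 0.3
measurement_cv: 0.2
seed: 1
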