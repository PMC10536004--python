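# teacat

Whole-body compartmental kinetics of green tea catechins: forward
simulation, weighted least-squares estimation of fractional transfer
coefficients, plasma residence time and fractional catabolic rate, synthetic
cohort generation, and gallation × hydroxylation factorial statistics.

## The problem

Green tea catechins — EGCG, EGC, EC and ECG — differ in two structural
attributes: esterification with gallic acid (gallation: EGCG, ECG) and the
number of B-ring hydroxyl groups (three: EGCG, EGC; two: EC, ECG). These
attributes change how the compounds move between body pools, which in turn
shapes where they can act. Because tissue sampling in humans is impractical,
tissue-level transfer rates must be inferred from plasma and urine alone.

`teacat` implements a 7-compartment linear model of this trafficking for
researchers in polyphenol pharmacokinetics: upper GI tract → small intestine
→ {large intestine → feces, liver → plasma}, with plasma exchanging with
extravascular tissues and draining through the kidneys into urine. The state
is the fraction of the ingested dose; transfers are first-order coefficients
L(I, J) in h⁻¹ (donor J, recipient I), assembled into a generator matrix M
with zero column sums (mass conservation is exact). Two derived quantities
summarize plasma exposure:

- plasma residence time RT = Θ[plasma, plasma], Θ = −A⁻¹, A the
  compartment-only rate matrix — the mean total time a molecule spends in
  plasma, counting re-entries from tissue, before irreversible loss;
- fractional catabolic rate FCR = 1/(60·RT), the fraction of the plasma pool
  lost irreversibly per minute.

Per subject × catechin, the five estimable transfers are fitted to 10 plasma
points (0–12 h) and 4 cumulative urine intervals (0–24 h) by weighted
nonlinear least squares with proportional-error weights, holding the fecal
route at exactly twice absorption. A fit is considered well identified when
the weighted SSR, the fractional standard deviations (SE/estimate < 0.5) and
the parameter correlations (< 0.8) all pass. Because the raw clinical data
are not public, a calibrated synthetic cohort generator (19 subjects, doses
290/87/39/28 mg, the study's exact sampling schedule) stands in for them and
makes every stage testable end to end.

## Worked example

`examples/residence_time_and_fcr.py` computes residence time and FCR for all
four catechins from the shipped truth parameters and cross-checks the matrix
algebra with a 100,000-particle stochastic simulation:

```
catechin   RT (h)   FCR (min^-1)   gallated
EGCG       0.606       0.02749   True
EGC        0.526       0.03171   False
EC         0.625       0.02667   False
ECG        1.250       0.01333   True

ECG matrix residence time : 1.2500 h
ECG particle oracle       : 1.2525 ± 0.0040 h (100k particles)
```

FCR is ordered EGC > EGCG ≈ EC > ECG: the combination of gallation and a
dihydroxylated B-ring (ECG) keeps a catechin in plasma longest, and the mean
FCR of trihydroxylated catechins exceeds the dihydroxylated mean by 48 %
(non-gallated exceed gallated by 43 %). Fitting one noisy synthetic subject
(`examples/fit_one_subject.py`) prints each estimated coefficient next to the
generative truth with its fractional standard deviation, e.g.

```
transfer                            estimate     truth    FSD
small_intestine -> liver              0.1794    0.1478   0.08
liver -> plasma                       1.3287    1.7049   0.14
plasma -> kidneys                     0.8064    0.9826   0.10
plasma -> extravascular               1.9494    2.0119   0.09
kidneys -> urine                      0.4920    0.3345   0.25
```

— estimates bracket the truth within a few tens of percent at 20 %
measurement noise, and the FSD column is the per-parameter uncertainty the
identifiability criteria act on. The other examples cover trajectory
simulation, the factorial ANOVA with Tukey letters, and structure selection
(is the extravascular compartment worth its parameters?).

A thin CLI wraps the same library for shell use:

```
teacat generate --n-subjects 19 --seed 1 --out cohort.csv
teacat fit cohort.csv --out fits.json
teacat summarize fits.json --out kinetics.csv
teacat anova kinetics.csv
teacat run --out results_dir          # all of the above, plus logs
```

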