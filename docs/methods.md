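# Methods

## Model

`teacat` implements a linear, donor-controlled, time-invariant compartmental
model of green tea catechin disposition after a single oral bolus. The final
structure has seven body pools — upper GI tract (stomach), small intestine,
large intestine, liver, plasma, kidneys, extravascular tissues — and three
terminal sinks (feces, urine, extravascular loss). The state is the *fraction
of the ingested dose* in each pool, so the system is dimensionless and
dose-independent; a fractional transfer coefficient L(I, J) (units h⁻¹) is the
fraction of donor pool J transferred to recipient I per hour. The generator
matrix M has L(I, J) off-diagonal and the negative total outflow on the
diagonal; every column sums to zero, which is what makes total mass (pools +
sinks) conserved exactly.

Assumptions inherited by everything downstream:

- first-order kinetics everywhere — no saturable uptake, no
  Michaelis–Menten terms, no protein-binding submodel;
- a unit bolus enters the upper GI pool at t = 0 and there is no other input
  (the study design suppressed dietary catechins);
- conjugated and unconjugated species are pooled, and catechins do not
  interconvert;
- the absorption:fecal split at the small intestine is fixed at 1:2, i.e.
  exactly one third of the dose is eventually absorbed, for every catechin.
  This linkage is enforced by substitution at all times, not just at
  initialization: the fecal coefficient is never a free parameter.

Alternative structures explored during model development are available as
variants: `no_extravascular` (the 6-compartment starting model), a portal-vein
pool inserted on the absorption route, a direct biliary liver→large-intestine
edge, and enterohepatic liver→small-intestine recirculation.

## Simulation

The default solver steps the matrix exponential over the (sorted) output
grid: x(t_{k+1}) = expm(M·Δt) x(t_k), using SciPy's Padé `expm`. This is exact
for the constant-coefficient system, smooth in the matrix entries (which the
finite-difference Jacobians in fitting rely on), and robust for *defective*
generators — duplicate transfer rates along a chain produce Jordan blocks, so
an eigendecomposition-based propagator is not usable in general. An
independent cross-check backend integrates the same system with DOP853 at
rtol 1e−13 / atol 1e−18; the two agree to better than 1e−6 relative error
(with a 1e−6 fraction-of-dose floor, far below observable resolution) across
wide random parameter ranges.

## Residence time and FCR

For the compartment-only submatrix A, Θ = −A⁻¹ gives mean occupancy times:
Θ[i, j] is the expected total time in pool i, counting re-entries, per unit
introduced into pool j. Plasma residence time is Θ[plasma, plasma]; in this
topology it reduces to

    RT = 1 / (k_pk + k_pe · (1 − r)),   r = k_ep / (k_ep + k_el),

the reciprocal of renal uptake plus net (non-returning) extravascular loss.
The fractional catabolic rate is FCR = 1/(60·RT), the fraction of the plasma
pool lost irreversibly per minute; the ×60 conversion is applied exactly once,
at this boundary — all coefficients remain per hour internally. The phrase
"time in plasma after entering via the liver" is read as describing the
physiological entry route: all plasma input arrives via the liver here, and
only the diagonal element satisfies FCR = 1/RT, so Θ[plasma, plasma] is used.

A continuous-time Markov jump-process oracle (particles started in plasma,
exponential holding times, plasma occupancy accumulated until absorption)
validates the matrix result to within Monte-Carlo error.

## Observables

Plasma is sampled instantaneously at 0, 0.25, 0.5, 1, 2, 3, 5, 8, 10, 12 h;
urine is a cumulative sink read at the ends of the 0–4, 4–8, 8–12, 12–24 h
collection intervals. Raw laboratory tables convert to fraction of dose by
concentration × plasma volume / dose (plasma volume from Nadler's
height/weight total-blood-volume formula × (1 − hematocrit), hematocrit 0.45,
all configurable — the choice rescales fractions per subject and cancels in
round-trip tests) and by concentration × interval volume, cumulated, / dose
for urine.

## Estimable parameter set

A per-series dataset holds 14 observations. Local identifiability analysis at
any admissible parameter set shows that the full 8-transfer fit is
degenerate:

- the large-intestine → feces drain moves material between two unsampled
  pools and has exactly zero sensitivity;
- the absorption cascade (upper GI → small intestine → liver → plasma)
  contributes a three-exponential convolution that is symmetric under
  permutation of its rates (the fixed 1:2 split makes the amplitude
  independent of the absorption rate), so the three rates are only
  identifiable up to relabeling and exactly singular when two coincide;
- the extravascular return and loss rates correlate above 0.98 with the
  plasma→tissue uptake they recirculate.

Defaults therefore fix: upper-GI emptying at 2.5 h⁻¹ (a gastric-emptying
scale, shared across catechins), large-intestine→feces at 0.5 h⁻¹, and the
extravascular return/loss pair at 0.6/0.6 h⁻¹ (return fraction r = 0.5). The
five estimated transfers — absorption (initialized at 0.30 h⁻¹, the
literature-based fractional absorption), liver→plasma, plasma→kidneys,
plasma→extravascular, kidneys→urine — are the routes the study's sampling
design can actually inform, with bounds [1e−6, 100] h⁻¹. All statuses are
plain data on the `ParameterSet` and can be overridden.

## Fitting

Weights are proportional-error: wᵢ = 1/(cv·max(yᵢ, y_floor))² with cv = 0.2
and y_floor the smallest positive observation of the series, so the zero
t = 0 plasma point keeps a finite weight. Estimation proceeds in stages that
operationalize the manual "adjust until the simulation tracks the data"
workflow deterministically:

1. *moment-matching initialization*: plasma AUC (trapezoid + terminal-slope
   tail) fixes plasma turnover via AUC ≈ 1/(3·FCR_h); total urinary recovery
   splits turnover between the renal and extravascular routes; the fraction
   of urine collected early sets the renal drain; the terminal slope
   approximates the small-intestine exit rate;
2. absorption-side coefficients refined against early (≤ 3 h) plasma points,
   then disposal-side coefficients against late plasma + urine;
3. joint bounded weighted least squares over all free coefficients.

Optimization runs on log-transformed coefficients (positivity, conditioning);
`scipy.optimize.least_squares` (trust-region reflective) does the work. The
covariance is inv(JᵀJ)·s² with s² = SSR_w/(n−p) from the log-space Jacobian at
the optimum; the log-space standard deviation *is* the fractional standard
deviation (FSD = SE/estimate, delta method), and the correlation matrix is
invariant under the diagonal back-transform. Noise-free data are refit to
machine precision; under 20 % proportional noise the per-coefficient 95 %
intervals cover truth at roughly 75–85 % (nonlinearity plus the chi-square
noise of s² at 9 degrees of freedom), which the test suite encodes as its
calibration contract.

A fit is *identifiable* when weighted SSR < 1e−5 (attainable only for
essentially noise-free data), every FSD < 0.5, and every off-diagonal
|correlation| < 0.8; it is *reportable* when it converged and meets the two
noise-robust criteria (FSD, correlation). On noisy cohorts the reportable
subset is dominated by the non-gallated catechins: the gallated renal pair
(plasma→kidneys ≈ 0.01 h⁻¹ feeding a slow renal drain) lives in a
product-coupled regime where the four cumulative urine points cannot separate
scale from shape, and its internal correlation sits near 0.94 regardless of
noise realization.

Structure comparison fits each candidate and ranks by (weighted SSR, max
FSD); added complexity is flagged as justified only when *both* improve over
the next-simpler candidate.

## Synthetic cohort

The generator emulates the study design: 19 adults (10 M / 9 F as labels
only; sex has no kinetic effect by construction), four catechins dosed at
290 / 87 / 39 / 28 mg (EGCG / EGC / EC / ECG), the exact sampling schedule
above. Subject-level coefficients are drawn lognormally, median-centred on
the truth values with CV 0.30 (adjustable edges only; linked edges follow
their anchors, so the 1:2 constraint holds exactly in every realized
subject). Observations carry multiplicative lognormal measurement error with
CV 0.20, then negatives are clamped and cumulative urine is restored to
monotone by running maximum. Both CVs are design choices — the source data
are not public — picked as typical of LC-MS pharmacokinetic panels, and are
configurable. Everything is reproducible from a single seed.

What the generator does *not* emulate: assay limits of detection, missing
samples, incomplete urine collections, conjugate speciation, microbial
degradation, or any sex effect. Passing tests therefore demonstrate internal
consistency of the pipeline under the model's own assumptions, not fidelity
to raw clinical data.

### Truth fixture calibration

The shipped per-catechin truth values (package data, produced once by
`scripts/calibrate_truth.py`, never recomputed at import) are calibrated so
the noise-free model reproduces the headline contrasts:

- relative FCRs solve the two ratio targets exactly — trihydroxylated vs
  dihydroxylated mean FCR = 1.48 and non-gallated vs gallated = 1.43 — with
  ECG = 1 and EC = 2 as anchors. An exact EGCG = EC is arithmetically
  incompatible with two different ratios (both would compare {EGC, X} to
  {X, ECG}), so the fixture carries a ~3 % EGCG–EC gap: the study-level
  "EGCG = EC" is a post-hoc non-difference, not an identity. The absolute
  scale (FCR_h of ECG = 0.8 h⁻¹, residence times 0.53–1.25 h) is typical of
  rapidly cleared polar compounds;
- the non-gallated : gallated mean plasma→kidneys ratio is exactly 150.
  Only group *means* are pinned, and the within-group splits
  (EGC 1.2 / EC 1.0; EGCG 0.011 / ECG 0.00367 h⁻¹) are spent on
  identifiability: they keep every catechin's extravascular route visible in
  plasma and raise the gallated renal drain the urinary target permits;
- the 150-fold urinary-recovery contrast cannot hold asymptotically given
  the FCR targets (it would equal 150 × the ratio of mean residence times
  ≈ 93), so it is met at the study's actual 24-h collection horizon: the
  shared gallated kidneys→urine coefficient is the single remaining degree
  of freedom, solved by 1-D root finding so the ratio of group-mean
  cumulative 24-h urine fractions is exactly 150. Gallated renal drainage is
  correspondingly slow (≈ 0.07 h⁻¹), consistent with the reported pattern of
  slower kidney-to-urine transfer for gallated catechins;
- consequences accepted as fixture properties: upper-GI emptying is
  compound-independent, and the plasma→extravascular ordering follows from
  the FCR arithmetic (gallated catechins lose almost nothing through the
  kidneys yet have only 1.43-fold lower FCR, so their extravascular loss is
  necessarily the larger).

## Statistics

The four catechins form a complete 2×2 gallation × trihydroxylation layout.
Subject-level responses (FCR, residence time, fitted transfers) are analyzed
by fixed-effects two-way ANOVA with interaction (statsmodels OLS, type-II
sums of squares), treating each subject × catechin value as an independent
observation — no repeated-measures structure, matching the source analysis.
Tukey's HSD across the four cells feeds a compact letter display
(insert-and-absorb; cells sharing a letter are not significantly different at
the family-wise α = 0.05; zero-variance responses are flagged degenerate and
get a single letter). The exploratory three-way model adds sex as a fixed
factor. No multiplicity correction is applied across responses. α = 0.05
throughout.

## Numerical choices and degenerate inputs

- Time grid for prediction: union of plasma times, urine interval ends and 0;
  `observe` never interpolates — requested times must be grid points.
- `least_squares` tolerances 1e−12 (xtol/ftol), max 2000 function
  evaluations for the joint stage; warm-start stages are capped at 200.
- Covariance requires cond(JᵀJ) < 1e12 and n_obs > n_params; otherwise the
  fit is flagged non-identifiable with infinite FSD, never a crash.
- An all-zero observation series fits to the bounds or flags
  non-identifiable; a missing compartment path to any sink raises with the
  trapped compartments named.
- Weight rescaling by any constant leaves estimates and FSDs unchanged
  (the residual-variance estimator absorbs the scale).

## Problem sizes

The test suite fits 5 × 76 noisy series for the recovery experiment (seeds
1–5), uses 100-particle-set random sweeps for the conservation and
backend-agreement oracles, a 100,000-particle run for the residence-time
oracle, and 25–60 replicates for the statistical null-rate properties; the
full suite runs in under two minutes on one CPU. The acceptance script
regenerates one 76-series cohort for the identifiability measurements.

## Known limitations

- The fixed 1:2 absorption:fecal linkage forces identical (33 %) absorption
  for all catechins; real bioavailability differs by compound. The linkage
  is the model's own stated constraint, kept for comparability.
- Gallated renal parameters are weakly identified by design of the study
  (tiny urinary recovery split over four pooled intervals); their fits are
  rarely reportable and their contrasts are recovered as geometric means
  over the cohort rather than per subject.
- The ANOVA treats repeated measures as independent; p-values on the
  synthetic cohort are qualitative reproductions (direction and α-level),
  not the study's exact values.
- Saturation, speciation, protein binding, and microbial metabolism are out
  of scope by construction.
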