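# Methods

This note documents the models, conventions and design choices behind
`akialert`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Detection and staging

AKI detection evaluates both KDIGO creatinine criteria at every
measurement time `t` of a series:

* **delta criterion**: `scr(t) − min scr over (t−48h, t] ≥ 0.3 mg/dL`;
* **ratio criterion**: `scr(t) ≥ 1.5 × min scr over (t−7d, t]`.

Windows are half-open, excluding a measurement exactly `window` hours
before `t` and including the one at `t` itself (which can never trigger
against itself: its delta is 0 and its ratio 1).  The earliest qualifying
time is the onset; the episode's baseline is frozen there as the 7-day
rolling minimum and anchors all later staging ratios, matching the
"increase from baseline" language of the staging rules.  When both
criteria fire at the same timestamp the recorded criterion is the delta
rule — a reporting convention that cannot shift the onset.  Criteria are
evaluated at measurement times only (the production analogue evaluates on
lab-result arrival); comparisons carry a 1e-9 relative tolerance so
decimal boundary cases (1.2 vs 1.5 × 0.8) behave as exact arithmetic.

Stages: 3 if kidney replacement therapy has started, the ratio reaches
3.0, or the 4.0 mg/dL rule holds; 2 for ratios in [2.0, 3.0); else 1.
The 4.0 mg/dL rule is ambiguous between "SCr value ≥ 4.0" (standard KDIGO
semantics, the default here) and "rise ≥ 4.0"; `stage3_scr_rule="delta"`
selects the literal-delta reading.

Measurement times are hours relative to admission and may be negative,
representing historic pre-admission creatinines; these participate in
rolling baselines, which is what makes a community-acquired episode
recognizable (see below).

## eGFR

The CKD-EPI creatinine equation, 2009 two-level form without the race
coefficient, is the default (the study population is entirely Han
Chinese, for whom the coefficient was never validated):
`141 × min(S/κ,1)^α × max(S/κ,1)^−1.209 × 0.993^age × 1.018[female]`,
with κ = 0.7/0.9 and α = −0.329/−0.411 for women/men.  The
race-coefficient variant and the 2021 race-free refit are available via
the `variant` argument.  Units: mg/dL in, mL/min/1.73 m² out.

## Eligibility and randomization

Seven exclusions are checked in the trial's listed order (the decision is
order-independent; only the reported reason depends on it): baseline
eGFR < 15, end-stage kidney disease at admission, kidney-transplant
history, community-acquired AKI, stay < 24 h, baseline SCr < 0.5 mg/dL,
repeat admission.  Community-acquired has no printed operational rule; the
package's rule is that the episode's 7-day baseline minimum was measured
before admission, or detection already fires at the first in-admission
measurement.

Randomization is 1:1 within four strata (medical/surgical × ICU/ward, in
the fixed order medical_icu, medical_ward, surgical_icu, surgical_ward).
Stratum `k` owns an independent stream seeded `20180101 + k` —
consecutive increments of the universal seed.  The generator algorithm is
unstated in the source trial; this package fixes NumPy's PCG64 and treats
(algorithm, seed scheme, draw index) as the reproducibility contract:
`randomize(stratum, i)` regenerates the stream from its seed, so
assignments are pure functions of their inputs, identical across runs and
platforms.  Default allocation is simple Bernoulli(1/2) draws; permuted
blocks of configurable even size are available.  Alert messages fill the
care-bundle template and are capped at three per admission (any emitted
message counts, regardless of day or episode).

## Outcomes

All "within N days" windows are `(t_rand, t_rand + 24N hours]` from the
randomization timestamp, not calendar days (timestamps exist in the data
model; calendar days would import a midnight convention the data do not
carry).  The eGFR at AKI and the eGFR at randomization are the same
quantity: randomization is triggered by the detection event.

Primary outcome: `Δ = eGFR_at_AKI − min eGFR over the 7-day window`, with
the minimum replaced by 0 when death occurs in the window, and the
relative form `Δ / eGFR_at_randomization`.  A patient with neither a
follow-up measurement nor an in-window death yields a missing value — no
imputation anywhere; denominators shrink instead.

Progression compares the stage at randomization with the highest
subsequent in-hospital stage and is recorded only when strictly higher.
Recovery at discharge has no printed definition; the package's default is
alive at discharge, dialysis-free, and last SCr < 1.5 × the episode
baseline (threshold configurable).  Alive-with-dialysis-dependency at 90
days is likewise a package convention: alive at day 90, dialysis started
within the 90-day window, and no recovery at discharge.  Anemia counts as
corrected only for hemoglobin strictly above 9.0 g/dL.  In-hospital
comparisons carry a 1-microsecond-scale slack so ISO-timestamp
round-tripping cannot flip an equality at the discharge instant.

## Statistics

* Risk differences are unpooled Wald: `100(p̂_a − p̂_b) ± z·SE`, no
  continuity correction, with Pearson χ² (1 df, uncorrected) p-values.
  This is the arithmetic that reproduces the published difference columns
  to their printed decimal; one published row (ultrasonography) prints a
  CI slightly different from Wald, and its CI is therefore not a target of
  the package's checks (its difference is).
* Mann-Whitney U counts pairs with `x > y` (+½ for ties).  For
  `n₁+n₂ ≤ 12` the p-value is exact, enumerating all group relabelings of
  the observed values (valid under ties; the permutation distribution of U
  is symmetric about n₁n₂/2, so the two-sided p is the mass at least as
  far from the center).  Larger samples use the tie-corrected normal
  approximation without continuity correction.  The exact small-sample
  path exists because the normal approximation is demonstrably poor for
  extreme splits (1 vs 9), where it can err by > 0.05.
* The Hodges-Lehmann shift is the median of all `n₁n₂` pairwise
  differences; its CI takes order statistics at the depths given by the
  normal approximation to the rank-sum null (the standard test
  inversion).  It backs the median-difference columns of the outcome
  tables.
* Subgroup analysis is univariate binary logistic regression per subgroup
  level (statsmodels' Newton/IRLS fit), with the interaction p from the
  Wald test of the arm×subgroup product term in the pooled fit.  Complete
  separation is flagged and the affected CI reported unbounded.  No
  multiple-testing correction, matching the trial's exploratory policy.
* Sample size: `n = ⌈2σ²(z₁₋α/₂+z₁₋β)²/Δ²⌉` per group; with σ = 13.4
  mL/min/1.73 m², Δ = 1.9, 90% power and two-sided α = 0.05 this gives
  1046, within the published 1050.  The published account describes "a
  2-tailed .025-level test for an overall significance level of α = .05",
  which is internally ambiguous; z₀.₉₇₅ = 1.96 is used because it is what
  reproduces the published requirement.  The enrolment total divides the
  evaluable 2n by (1 − attrition) and rounds up to a granularity of 100:
  2×1050 at 30% attrition gives 3000.

## Synthetic cohorts

The generator emulates the study conditions, not kidney physiology:

* ~1.4 AKI episodes per 100 admissions (configurable), stage mix
  50/25/25%, baseline SCr log-normal with median 0.87 mg/dL (σ_log 0.35,
  matching the published baseline IQR roughly), age ≈ N(64, 13) clipped
  to [18, 95], 70.7% male, 60.6% ICU, ~11% 7-day mortality and ~12% 7-day
  dialysis among AKI patients, and per-arm care-process event
  probabilities equal to the trial's observed proportions.
* Lab cadence: one draw per ~24 h on wards, 6–12 h in ICU — the trial does
  not describe lab frequency; these are plausible ward/ICU practice and
  exercise the window logic.
* Non-AKI trajectories are flat on the log scale with multiplicative
  noise whose relative amplitude is clipped to `min(2.5·CV, 0.13/baseline)`
  (CV default 5%).  The clip makes non-triggering a guarantee, not a
  probability: the within-series range can reach neither 0.3 mg/dL nor a
  1.5× ratio.
* Injected AKI replaces post-onset values with an analytically controlled
  ramp-plateau-recovery profile.  The first post-onset value is already
  1.55× the trailing 7-day minimum, so detection fires exactly at the
  requested onset and freezes that minimum as the baseline; the peak ratio
  is drawn inside the requested stage's band (1.55–1.85 / 2.1–2.8 / ≥3.2)
  and, for stages 1–2, capped below the 4.0 mg/dL value rule (baselines
  are redrawn above 2.0/1.7 mg/dL for stages 1/2 to keep the band
  reachable).  Highest stage therefore equals the requested stage by
  construction; dialysis, which forces stage 3, is injected only for
  stage-3 patients.  Death inside the admission truncates the series, so
  the recorded ground-truth stage is recomputed on the truncated series
  (the injected stage is kept in a separate column).
* Reproducibility: admission `i` draws from the substream seeded
  `(seed, i)`; cohorts are identical across runs and independent of
  iteration order.  Arm-dependent events are drawn after screening and
  randomizing each episode with the package's own randomizer, so the
  pipeline re-derives the same assignments and the ground truth is exact
  per patient.
* Not emulated: comorbidity correlations, clinician behaviour beyond the
  configured event probabilities, repeat admissions (the repeat-admission
  exclusion is exercised in unit tests via the screening API), assay
  drift, urine-output criteria.  Passing tests on these cohorts show the
  machinery is correct under controlled conditions; they say nothing
  about how real creatinine trajectories distribute, and the published
  primary-outcome medians are not reproducible without the patient-level
  data.

## Problem sizes and numerical choices

The calibration checks use: 600 null-configuration replicate cohorts of
150 admissions (all-AKI, equal arm probabilities) for the χ²/Mann-Whitney
type-I rates; 1000 random ≤12-point series for the detection oracle;
exhaustive permutation comparisons for all splits with n₁+n₂ ≤ 10; and a
5000-admission cohort for the end-to-end runtime check — sizes chosen so
the whole acceptance script completes in about two minutes while keeping
Monte-Carlo error well inside the asserted bands.  Logistic fits converge
by statsmodels' default Newton criteria (relative tolerance 1e-8, ≤ 35
iterations; the package caps at 100).  Ties between detection criteria,
degenerate inputs (empty windows, zero denominators, empty cohorts) and
separation are all explicit error or missing-value paths rather than
silent defaults.

## Known limitations

The generator's trajectory model is deliberately schematic (flat +
controlled rise); it cannot probe detection behaviour under slow drifts,
assay noise near thresholds, or dense oscillating series.  The
community-acquired rule, recovery rule and 90-day dialysis-dependency
rule are documented conventions, not published definitions.  Urine-output
KDIGO criteria are out of scope, as in the source trial.
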