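# Methods

This note documents the modelling choices behind `akidetect`: the exact
semantics of the staging rules on irregular data, the operational
parameters and their defaults, what the synthetic cohort generator does and
does not emulate, and the numerical conventions used throughout.

## Observation window and cohort construction

ICU admission and discharge times are generally not reconstructible from an
archived PDMS, so each patient's **observation window** runs from the first
available vital-sign timestamp to the last signal of any kind (vitals,
labs, urine, weight, dialysis), capped at 14 days. All detection is
restricted to this window; "day k" in every cohort table means the bin
`[k-1, k)` days from the individual window start.

Screening applies three exclusion rules in a fixed order, and a patient
failing several is attributed to the **first** match only — this makes the
accounting deterministic and guarantees the conservation invariant
`screened == included + sum(excluded per rule)`:

1. `non_cardiac_surgery` — surgery type other than cardiac;
2. `missing_or_invalid_data` — sex unusable, age outside a plausible band
   (default [18, 110] years, configurable), or no body weight at all when no
   fallback weight is configured (urine output could not be normalised);
3. `improper_data_for_use` — dialysis before the first ICU signal, no vital
   timestamps, a degenerate signal span, or too few AKI-relevant signals
   (default: at least one creatinine value and at least two urine records;
   no established quantification exists, so the bound is configurable).

## Creatinine criterion

- **Baseline** = the first creatinine value inside the observation window.
  Pre-operative values are rarely documented in the same system, and
  creatinine shortly after surgery is still close to baseline because
  retention products accumulate over hours to days.
- **Absolute-increase rules** (the 0.3 mg/dl stage-1 rise and the 0.5 mg/dl
  component of the stage-3 rule) compare against the *rolling minimum over
  the trailing 48 h* of draws, over the half-open interval `(t - 48 h, t]` —
  not against the admission baseline. This follows the criterion's intent
  ("increase within 48 hours") and keeps the rule sensitive after recovery.
- **Multiplier bands** are the half-open partition `[1.5, 2.0)`, `[2.0,
  3.0)`, `[3.0, inf)`. Printed renderings of the bands as 1.5–1.9 and
  2.0–2.9 are the same partition truncated to one decimal; treating them as
  closed bands would leave values such as 1.95 unstageable.
- The stage-3 cell is parsed as `multiplier >= 3.0 OR (value >= 4.0 mg/dl
  AND 48 h rise >= 0.5 mg/dl)` — the OR-of-AND reading consistent with the
  consensus definition; a flat left-to-right reading would make the 4.0
  mg/dl branch unreachable.
- The criterion is evaluated **at creatinine record times only**: between
  draws there is no information, and holding a stage between draws would
  conflate the criterion with the cumulative-maximum view, which is
  computed separately.

## Urine criterion

Urine charting records carry the volume accrued since the previous record
(the first record accrues from the window start). The rate model treats
each volume as **uniformly accrued over its interval**; the rate over a
trailing window `[t - w, t]` is the overlap-allocated volume divided by
`interpolated_weight(t) × w`. Cumulative volume and covered time are
piecewise linear, so each window evaluation is two interpolations — this is
exactly equivalent to (and tested against) a brute-force minute-level
allocator.

Staging uses the **window-average** reading with strict inequalities: stage
3 when the 24 h average is < 0.3 ml/kg/h, else stage 2 when the 12 h
average is < 0.5, else stage 1 when the 6 h average is < 0.5. The
alternative reading — instantaneous rate persistently below threshold for
the full duration — is stricter on noisy charting and is not implemented;
the window-average form is what an over-time plot of "calculated urine
output over different time windows" computes. The 24 h window continues to
fire while the condition persists (a 48 h span cap applies to evidence
reporting only, not to detection).

Two operational guards prevent artefacts of missing documentation
(defaults; both configurable):

- an accrual interval longer than `max_documentation_gap` = 6 h contributes
  volume but not *coverage*;
- a window is evaluated only when covered for at least
  `window_coverage_min` = 0.7 of its length, and only when it lies entirely
  inside the observation window.

Body weight is linearly interpolated between records and held constant
beyond the first/last record — linear extrapolation over a 14-day window
can produce implausible weights.

## Combination, evaluation grid and summaries

Evaluation times are an hourly grid from the window start (step
configurable) united with every creatinine, urine and dialysis record time.
The combined stage at a time is the maximum over the three criteria; when
several criteria tie at the same stage and instant, attribution follows the
precedence dialysis > urine > creatinine (dialysis is the most explicit
signal, creatinine the most derived). Dialysis implies stage 3 from the
first in-window event onward.

Per patient, `first_AKI_*` comes from the earliest combined detection,
`max_AKI_stage` is the highest combined stage and `max_AKI_time` the first
time it was reached. `criteria_at_max` collects every criterion that at any
time indicated the maximum stage; `first_criterion_at_max` is the earliest
of these (same tie precedence).

Two time-per-stage notions are kept apart in the per-patient frame:
`reach_s` = first time the cumulative stage is ≥ s (used for daily
evolution bins and nephrotoxic-timing flags), and `visit_s` = first time
the cumulative stage equals s exactly (used for transition medians — a
patient jumping 0 → 2 never visits stage 1 and contributes to no 1 → j
transition).

## Cohort analytics

- Percentages are reported to one decimal, with the stated subgroup as
  denominator.
- Detection curves for first/max AKI are empirical cumulative-incidence
  step functions over the whole cohort. Every patient is observed over
  their complete window, so a Kaplan–Meier estimator would reduce to this
  empirical CDF; no censoring adjustment is applied.
- The criterion-contribution table has two blocks that each partition the
  AKI patients: by the *set* of criteria that ever indicated the maximum
  stage (seven combinations), and by the single criterion that indicated it
  first.
- Subgroup comparisons use the Wilcoxon rank-sum test for numeric
  covariates (exact enumeration when the pooled sample has ≤ 20
  observations, otherwise the tie-corrected normal approximation with
  continuity correction) and Pearson's chi-squared test without continuity
  correction for categorical ones. No multiplicity correction is applied.
  Both tests are implemented in `akidetect.stats` and cross-checked against
  independent reference implementations to 1e-8 in the test suite.
- "Length of ICU stay" is operationalised as observation-window length in
  days — the same signal-span approximation used for windowing.

## Free-text mapping

Comorbidity mapping is dictionary-based (case-insensitive regular
expressions for German and English phrasings of the 14 AKI-related ICD-10
codes I25, I10, E78, E14, I35, I34, I48, N18, E66, I70, J44, G47, I33,
I71), not learned NLP: the mapping protocol is a curated table and must be
auditable. Guard patterns can only *veto* a match, never add one. The
documented-AKI marker accepts explicit kidney phrases ("akutes
Nierenversagen", "acute kidney injury", "acute renal failure") and the bare
token "AKI" only outside valve context — in German cardiac-surgery records
"AKI" frequently abbreviates *Aortenklappeninsuffizienz* (aortic valve
regurgitation), and that collision must never inflate documented-AKI
counts. The shipped dictionary covers main-text diagnoses plus obvious
synonyms; it is a bundled, editable YAML file, and the 40-snippet labelled
fixture in the test suite is its regression surface. Nephrotoxic drug
matching is whole-word and case-insensitive over a small editable catalog
(ibuprofen and vancomycin being the clinically dominant entries).

## Synthetic cohorts and ground truth

The generator emulates the *charting process* of a cardiac-surgery ICU, not
kidney physiology: signals are piecewise-parametric, which is sufficient to
exercise every staging rule.

Study conditions (defaults):

- maximum-stage mix (0.346, 0.176, 0.305, 0.173) for stages 0–3;
- stay lengths log-normal with median 7.8 days (log-sd 0.527, matching an
  IQR of roughly 5.8–11.8 days), capped at 14 days; stays of planted-AKI
  patients are at least 3 days so the episode fits its windows;
- urine charting ≈ 10.6 records/patient-day with gamma-distributed gaps
  (shape 4), putting the 95th percentile of mean gaps below 4.5 h;
  charting tightens to ≈ hourly during oliguria with a record at the rate
  change — oliguric patients are monitored closely in practice, and without
  boundary records interval accrual smears pre-onset volume across the
  onset, which would systematically hide short stage-1 episodes;
- creatinine draws roughly twice daily; weights daily; documentation
  dropout 2 % (a dropped urine record merges its volume into the next one);
- an explicit AKI diagnosis text is emitted for 2.75 % of true-AKI patients
  (the documented-incidence-to-true-incidence ratio 1.8 % / 65.4 %), along
  with comorbidity phrases and "Aortenklappeninsuffizienz" decoys.

Planted episodes use one primary mechanism (urine 70 %, creatinine 25 %,
dialysis 5 % — dialysis only for stage 3), optionally a secondary
creatinine ramp to the same stage. Oliguria segments run at 0.45 (stage 1,
7–9 h), 0.40 (stage 2, 13–20 h) or 0.20 ml/kg/h (stage 3, 26–40 h);
creatinine ramps rise linearly over 18–30 h to a peak inside the target
multiplier band, then plateau.

**Noise is truncated so that it can never change the planted stage.**
Urine noise is multiplicative log-normal (σ = 0.2, truncated at 1.8 σ) on
normal-diuresis intervals only and suppressed inside oliguria segments;
with baseline diuresis ≥ 1.0 ml/kg/h the noise floor keeps every normal
window average above 0.5, and the episode durations are calibrated so the
next-higher window rule cannot fire even at the floor. Creatinine noise is
relative (σ = 0.02, truncated at 2 σ); because the baseline itself is a
noisy draw, observed multipliers can be rescaled by up to
(1 + 2σ)/(1 − 2σ) ≈ 1.08, and the planted peak bands (1.60–1.80,
2.20–2.60, 3.30–3.90) leave margin for exactly that.

**Ground truth is analytic, not detector-derived.** For each planted
signal, the first time each window-average rule is met is solved in closed
form from the piecewise-linear cumulative volume (crossings of
`R(t) − R(t − w)` against `threshold × w`), and creatinine crossings from
the ramp geometry; dialysis truth is the event time. On noise-free,
gapless (hourly) variants the detector recovers the planted maximum stage
for 100 % of patients with onsets within one evaluation-grid step of the
analytic times; under the default noise and charting irregularity,
maximum-stage agreement is bounded below at 95 % in the test suite (a
regression bound on the generator-detector pair, not a clinical claim).

What the generator deliberately does **not** model: creatinine kinetics
(no ODE — ramps are geometric), diuretic-driven urine dynamics, systematic
(non-random) documentation failure, inter-signal physiological coupling,
and readmissions. Passing tests therefore demonstrate correctness of the
rule engine and pipeline on realistic charting *structure*, not clinical
performance on real patients.

## Problem sizes and numerics

The test suite runs cohorts of 100–500 synthetic patients (recovery checks
at n = 200, charting calibration at n = 500), 200 randomised fixtures for
the urine-allocator oracle (agreement < 1e-9 relative), and 100 randomised
instances per structural invariant and statistical cross-check; the whole
suite completes in well under a minute. Evaluation uses an hourly grid by
default (`eval_grid_step`); timestamps are timezone-naive and converted to
float hours relative to the window start internally. Equality at a
threshold is never a detection (all staging inequalities are strict in the
direction printed above), and crossing times returned by the analytic
solver mark where the average *reaches* a threshold — a strict rule is met
immediately after, hence the one-grid-step tolerance in the recovery
checks.

## Known limitations

- The urine window-average reading and the hybrid evaluation grid are
  documented conventions; other implementations may use persistently-below
  semantics or charting-time-only evaluation and will stage borderline
  episodes differently.
- Exclusion attribution is first-match; cohorts with many multi-rule
  patients are summarised differently by cascades with other orderings.
- The ICD-10 dictionary is deliberately small and auditable; recall on
  free-text conventions outside its phrase list is zero by construction.
- No AKI episode merging or recovery detection: the per-patient summary is
  first/max only.
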