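# Methods

This note documents the modeling choices behind `ewsbench`: what each stage
assumes, which defaults matter, what the synthetic generator does and does
not emulate, and the numerical conventions that make results reproducible.

## Unit of analysis and labeling

The unit of analysis is the **ward observation**, not the patient. A
snapshot is created at every time a vital sign is charted while the patient
is located on the ward (laboratory results alone do not create snapshots;
scores are anchored to observation times). Each snapshot is labeled 1 when
the patient's first outcome event falls in the forward window `(t, t+24 h]`,
and observations at or after the event are excluded. The window is closed on
the right: an event exactly 24 h after an observation is a positive.
Observations in the final 24 h before an uneventful discharge are retained
as negatives; a `horizon_h` parameter varies the window, and a patient-level
sensitivity analysis (maximum score per patient) can be built from the same
labeled frame.

Snapshots are assembled by last-observation-carried-forward with per-class
staleness horizons: vitals (including AVPU and supplemental O2) carry 24 h,
labs 48 h, always within the same encounter. Beyond its horizon a slot is
absent, scores treat it as contributing nothing, and the per-system
`completeness` fraction records how much of the system's input was present.
Horizons are configuration (`LocfConfig`), and a horizon of zero reduces
snapshots to same-timestamp values only — a tested invariant.

Timestamps are ISO-8601 at minute resolution in a single implicit timezone
per cohort; durations are minutes internally.

## Score band tables

All five systems are pure functions of a snapshot and a declarative
`ScoreConfig`: a list of bands with **explicit open/closed endpoints** so no
value can fall into two bands, validated at load time (overlap check for all
systems; full real-line coverage, including a 0-point band, for the
aggregate systems). Printed thresholds are taken as closed on the side of
the printed value (e.g. NEWS "21–24 → 2 points" is `[21, 25)`).

The shipped tables follow the systems' source publications: MEWS (Subbe),
NEWS (the national score), MEOWS red/yellow (Singh), MEWC criteria (Mhyre)
and MEWT severe/non-severe (Shields). Every value is overridable through a
YAML config so a site variant can be matched exactly. Conventions that
needed a decision:

* **Ordinalization of trigger systems.** For ROC analysis, MEOWS and MEWT
  are scored `(#mild) + 2·(#marked)` and MEWC counts criteria; the published
  trigger rule is then exactly the cutoff ≥ 2 (MEOWS, MEWT) or ≥ 1 (MEWC).
  This is also how graded trigger severity is usually tabulated.
* **Tier precedence.** Where a severe band sits inside a milder band's range
  (MEWT heart rate > 130 severe vs > 110 non-severe), the shipped config
  encodes disjoint ranges (`(110, 130]` non-severe, `(130, ∞)` severe): the
  higher tier governs, and the overlap checker stays decidable.
* **Subjective elements** of the obstetric systems (nursing concern,
  non-remitting headache) are not representable in coded EHR streams and are
  excluded.
* **Derived inputs.** MEWT's mean arterial pressure is `(SBP + 2·DBP)/3`,
  computed only when both pressures are present. The MEWC oliguria
  criterion evaluates the urine rate `URINE_OUT/12` mL/h and only when a
  *positive* quantified 12-h volume is charted: unquantified urine is
  recorded as 0 by convention, and scoring the placeholder literally would
  trigger on nearly every observation.
* **Missing variables** contribute no points/trigger and lower
  completeness — the deployed-score convention.
* **MEWT persistence.** The original MEWT asks for abnormality sustained
  > 20 min; this is not enforced at snapshot level (single-observation
  scoring), matching how snapshot-anchored comparisons are run.

Two scoring paths exist deliberately: a per-snapshot linear scan over bands
(the reference semantics) and a vectorized batch path used by the pipeline;
their equality on random snapshots is a property test.

Machine-learning risk scores (e.g. a random-forest deterioration model) are
represented by a pluggable interface — `fit(snapshots, labels)` /
`predict(snapshots) → probability` — with a random-forest surrogate
(`SurrogateRiskModel`, scikit-learn, median imputation, seed-deterministic)
for exercising the continuous-score path. The surrogate is this package's
own construction for pipeline testing, not a reproduction of any external
model's weights.

## Outcome phenotypes

**Deterioration** emits at most one event per encounter (the first): ICU
entry when a ward interval is immediately followed by ICU, or via one or
more consecutive labor-&-delivery intervals when ICU entry is ≤ 24 h after
leaving the ward; otherwise death during the encounter with prior ward care,
at `death_time`. Direct L&D→ICU chains that never touched the ward are not
events. A death more than 24 h after the last ward observation is still an
event, but produces no positively labeled observation — the labeling window
takes care of it.

**Infection** uses calendar days (local midnight truncation): a
blood-culture order on day *d* qualifies when some IV-antibiotic day *d₀*
with |d₀ − d| ≤ 2 starts an antibiotic course (IV or oral) running ≥ 4
consecutive days, or on every day from *d₀* through the day before
discharge. A course starting on the discharge day itself cannot use the
censoring clause (an empty day range does not count as "through the day
before discharge"). Gaps of one or more antibiotic-free days break the
streak. The event time anchor is the earliest qualifying culture-order time;
by default only the first episode per encounter is emitted (later cultures
can be emitted with a minimum separation of one day). The detector is
verified against exhaustive day-by-day enumeration on random ledgers.

## Evaluation statistics

AUC uses the midrank estimator (ties one half), identical to O(n²) pair
counting — a tested equivalence. Variance and paired comparisons use the
DeLong placement values; constant scores give AUC exactly 0.5 with zero
variance, and comparing a score with itself gives difference 0, p = 1
exactly. Two-sided p-values come from the normal reference; no
multiple-testing adjustment is applied to the pairwise matrix. 95% CIs are
`AUC ± 1.96·SE` truncated to [0, 1]. The alert rule is `score ≥ threshold`
everywhere; threshold tables default to all distinct score values, and
efficiency curves report (fraction of observations alerting, sensitivity)
per distinct threshold, ending at (1, 1).

Cohort characteristic tables report median (IQR) with Wilcoxon rank-sum
p-values for continuous covariates and n (%) with chi-squared p-values for
categorical ones. Percentages are rounded to one decimal, half away from
zero, matching clinical-table convention.

## Synthetic cohort generator

The generator emulates the *structure* of obstetric ward EHR data, not its
full physiology:

* **Baselines.** Patient-level baselines are normal around published
  obstetric medians with SDs derived from IQRs (IQR/1.349): HR 85 (σ 14.1),
  RR 18 (1.5), T 36.6 °C (0.37), SBP 117 (16.3), DBP 67 (11.9), SpO2 98
  (1.5, clipped at 100), fetal HR 140 for an antepartum fraction (30%).
  70% of the marginal variance is between patients and 30% within
  (ICC ≈ 0.49), preserving the configured marginal SD. Labs are log-normal
  (normal for hemoglobin) around their published medians. Observation noise
  is independent across charting times (an AR(1) option is deliberately
  omitted from the default: only marginal distributions are being matched).
* **Flow.** Every patient starts in L&D (2–12 h) then transfers to the
  ward; charting is every 4 h ± 1 h; labs daily. Length of stay is
  log-normal around median 3 d (2–3) without events and 8 d (6–12) with.
* **Deterioration.** A prevalence-controlled fraction receives a transfer
  chain — direct ward→ICU (75%), via L&D within 24 h (15%), deliberately
  non-qualifying > 24 h dwell (5%), death on the ward (5%), plus an optional
  "death 36 h after the last ward observation" chain — with an additive
  linear drift over the final 12 h before the event: HR +25, RR +8, SBP −20,
  T +1.2, scaled by `drift_scale` and clipped to plausibility bounds.
* **Infection.** Infected patients get a culture order at onset, an IV
  course starting within ±1 day that satisfies the infection criterion by
  construction, and fever/tachycardia drift (T +1.0, HR +20) around onset.
  5% of non-infected patients receive decoy courses (2-day runs without a
  culture, or IV starting 3 days after the culture) that must not satisfy
  the criterion.
* **Reproducibility.** Each patient draws from a substream keyed by
  `(seed, patient index)`: identical seeds give byte-identical CSVs, and
  enlarging the cohort never perturbs existing patients.

Default prevalences are the published study scale (0.2% deterioration,
0.4% infection); `SimConfig.test_scale()` raises both to 5% for
development-scale runs (n ≈ 2000), since stable AUCs at 0.2% prevalence
would need cohort sizes far beyond a desk-scale test suite. The problem
sizes used by the test suite and the acceptance script — n = 2000 for the
drift sweep, n = 1000 for null-calibration replicates, n = 500 for examples
— are the package's chosen development scale.

**What passing tests do and do not show.** The generator matches marginal
distributions, event-stream logic and ADT structure, so green tests
demonstrate that the pipeline's logic (band lookups, temporal phenotype
rules, labeling, rank statistics) is correct and that injected signal is
recovered in the right order. They do *not* validate clinical performance:
real pre-event physiology is not a clean linear ramp, real charting is
state-dependent (sicker patients are measured more often), vitals are
autocorrelated, and documentation artifacts abound. AUC values on synthetic
cohorts therefore characterize the generator, not the scores' real-world
accuracy.

## Numerical conventions and degenerate inputs

* Band endpoints are explicit; the coverage checker requires adjacent bands
  to touch with exactly one closed side.
* Fully missing snapshots score 0 with completeness 0; single-class label
  vectors raise `degenerate_labels` rather than returning a value; a zero
  horizon is rejected.
* Score ties are everywhere (ordinal scores): midranks handle them
  exactly, which is why trapezoidal integration of the full threshold sweep
  reproduces the AUC to 1e-9.
* Out-of-bounds raw values (plausibility table in `data_model`) are
  rejected at read time with a reason, never silently dropped, and never
  reach scoring.

## Known limitations

* **Clustered observations.** All evaluation statistics treat observations
  as independent, but repeated observations of one patient share a baseline
  (ICC ≈ 0.49 in the generator; real wards similar). DeLong variances are
  therefore anti-conservative at the observation level: in 20-replicate
  null experiments the nominal 95% CI covers 0.5 in roughly 75–90% of
  replicates, consistent with a design effect of ~3 from ~5–6 positive
  observations per event patient. Patient-level resampling would be needed
  for calibrated uncertainty; the observation-level convention is retained
  because it is how these scores are compared in practice.
* **Coarse trigger scores under ramped drift.** MEWC takes only a handful
  of values; with a 12 h linear ramp and a 24 h label window, only
  observations in the last few hours before an event cross its thresholds,
  so its synthetic-cohort AUC (~0.59 at 2× drift) sits below the aggregate
  scores'. This is a property of the drift model and score coarseness, not
  of the implementation — the ordering of systems is stable across seeds.
* The infection criterion is a pharmacy/microbiology proxy; the generator
  plants courses that satisfy it by construction, so sensitivity/specificity
  of the *criterion itself* against true infection status is outside scope.
* No calibration analysis, decision-curve analysis, or time-dependent ROC
  beyond the fixed window; no HL7/FHIR ingestion or de-identification.
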