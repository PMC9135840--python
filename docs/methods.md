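# Methods

This note documents the statistical procedures, the synthetic-data
generator, and the design decisions taken where the underlying study design
left room for interpretation.

## Study design implemented

The package implements a retrospective new-user, active-comparator cohort
analysis over electronic health records. The unit of analysis is one
follow-up episode per patient, starting at the index date *t₀* (the first
prescription of a target DAA within the 2009–2017 study window) and ending
at the first of four dates: outcome occurrence, treatment-era end, change
to a different prescription pattern, or study end.

### Date semantics

Dates are calendar dates with integer-day arithmetic; no times of day
exist. "Before *t₀*" is strict (`date < t0`) for diagnoses and procedures;
the 90-day lookback is the inclusive window `[t0-90, t0-1]`. The *t₀*-day
laboratory value is never used — neither as a baseline candidate nor as an
event — because a same-day measurement cannot be ordered relative to the
first dispensing. The history requirement ("records from at least 90 days
before *t₀*") is inclusive: a first record on exactly `t0-90` qualifies,
and the first record is the minimum date over all four dated tables
(prescriptions, labs, diagnoses, procedures), since an administrative
contact of any kind demonstrates observability.

### Exclusion counting

Per-criterion attrition counts are evaluated independently, so one patient
can contribute to several counts (duplicate counting, matching how such
flowcharts are published); the analyzable cohort removes the union. A
consequence, verified by a property test, is that the final cohort is
invariant to the order in which criteria are applied. Criterion 1 (pre-
index eGFR < 45) considers serum-creatinine-converted values as well as
recorded eGFR, since the conversion rule is stated generally. Criterion 6
(missing mandatory concomitants) is evaluated only for patients whose
*t₀*-day DAA set is pattern-compatible; an impermissible multi-DAA set is
counted under criterion 5 alone, as pattern rules are undefined for it.

### Exposure patterns and drug eras

The ten patterns are keyed on the anchor DAA(s) dispensed on *t₀*;
mandatory partners and concomitants are looked for within ±30 days of
*t₀*, both ends inclusive. OBV/PTV/r with versus without ribavirin in that
window separates patterns 8 and 9. For the mandatory pairs (DCV+ASV,
EBV+GZR) the partner may appear either on *t₀* itself or elsewhere in the
window.

Time-at-risk is the standard drug-era construction: a prescription covers
`[start, start + days_supply - 1]`; a successor starting at most 28 days
after the running supply end extends the era; the final supply end gains a
single 7-day grace period, truncated at study end. Only the first era from
*t₀* is analysed (single-follow-up design). "The treatment period of
asunaprevir/grazoprevir is proportional to that of its partner" is
implemented as identity with the partner's era (DCV for ASV, EBV for GZR):
these drugs are only co-administered with their partner, so the partner's
era is the natural carrier. An alternative reading (pro-rating supply
days) could not be ruled out from the design description; identity was
chosen as the simpler and more conventional rule.

A pattern change censors at the day *before* the first foreign-pattern DAA
prescription inside the era, because exposure on the change day itself is
ambiguous. Ties between the outcome and any censoring date on the same day
record the event, mirroring the "first of the following dates" ordering
that lists the outcome first; among censoring reasons the tie-break order
is treatment end, pattern change, study end, except that an era truncated
by the study window is reported as study-end censoring.

### Outcome derivation

One eGFR value per patient-day: recorded eGFR values take precedence, with
same-day multiples averaged; days with only serum creatinine use the mean
converted value. The conversion is the Japanese GFR estimating equation
(194·sCRE⁻¹·⁰⁹⁴·age⁻⁰·²⁸⁷, ×0.739 for women) with age in completed years
*at the laboratory date* — the equation is a per-measurement conversion,
so age is not frozen at *t₀*. KDIGO category assignment compares the raw
floating-point value against the printed boundaries with inclusive lower
bounds (90, 60, 45, 30, 15); no rounding is applied before
categorisation. The baseline is the value from the latest patient-day in
`[t0-90, t0-1]`, regardless of whether that day's value was recorded or
converted. The primary outcome is a drop of ≥ 1 category from baseline;
the sensitivity outcome requires ≥ 2. Event days at threshold 2 are
provably a subset of (and no earlier than) those at threshold 1.

### Inference

Person-years are follow-up days divided by 365.25, exactly 0 for episodes
ending on *t₀*. For the rate ratio of a pattern versus the control
(LDV/SOF), the analysis conditions on the total event count: with
person-times PYₑ and PY_c, the exposed count is Binomial(n, p) with
p = IRR·PYₑ/(IRR·PYₑ + PY_c). The two-sided p-value sums all outcome
probabilities not exceeding the observed one under the null (the
minimum-likelihood convention), and the 95% interval inverts the
Clopper–Pearson interval for p. The source study does not name its
interval or test; the exact conditional method was chosen for validity at
the small event counts involved (several patterns with fewer than 20
patients), and is deliberately conservative. A log-normal (Wald) interval
is available via `ci_method="wald"` for comparison. Significance is
reported at the study's p < 0.01 criterion; raw p-values are always
emitted and no multiplicity adjustment is applied (none was applied in
the design being implemented). Baseline comparisons use the Wilcoxon
rank-sum test (mid-ranks; exact enumeration for small untied samples,
normal approximation with continuity correction otherwise, as provided by
`scipy.stats.mannwhitneyu(method="auto")`) and Fisher's exact test for
sex. Report masking follows the source database's publication rule:
counts below 10 render as "< 10" and percentages derived from a masked
count as "NA".

Degenerate cases: zero person-time in either arm yields a not-available
rate ratio; zero exposed events give IRR 0 with a finite upper bound; zero
control events give an infinite point estimate with an informative lower
bound; zero events overall give p = 1.

## Synthetic-data generator

The generator emulates the structural features the pipeline relies on, not
hepatitis-C disease biology:

- **Population.** Ages from a truncated normal (65 ± 12 years, bounds
  20–95), 57% female, baseline eGFR truncated normal (75 ± 13, bounds
  46–130) — figures chosen to echo the published baseline tables of the
  emulated cohort (elderly, majority female, median eGFR ≈ 73–76).
- **Pattern mixture.** Defaults proportional to the published per-pattern
  cohort sizes, plus a 15% non-user background.
- **Records.** The era drug is dispensed in 28-day supplies with 0–7-day
  refill jitter over the intended regimen length (84 days; 168 for
  DCV+ASV); concomitants are dispensed on *t₀*. Kidney-function tests
  occur every 10–30 days (mean 20), matching the reported testing cadence
  of roughly 4 tests per ~87-day follow-up; 20% of results arrive as serum
  creatinine (back-computed by inverting the estimating equation) and 5%
  of eGFR days carry a same-day duplicate.
- **Exclusion carriers.** Independent per-criterion carrier flags
  (diabetes 20%, hypertension 35%, heart failure 8%, CKD/renal failure
  5%, dialysis/transplant 1%, missing baseline labs 15%) inject the
  corresponding records; prevalences were set so the union of exclusions
  removes a majority of new users, echoing the attrition scale of the
  emulated study. Ten percent of users draw a shortened (< 90-day)
  history.
- **Events.** A latent exponential event time per patient with rate
  `event_rate_control × rate_ratio_per_pattern[pattern]` per person-year
  (control default 0.5/py). An event is only observable on a test day: on
  the first test day at or after the latent time the generated value falls
  strictly below the baseline category's lower bound (one category down;
  25% of events fall two). Non-event values fluctuate inside the baseline
  category with a 0.2-unit margin, so ground truth is unambiguous. This
  reproduces the interval-censored detection inherent in outcomes read off
  measurement times.
- **Reproducibility.** One global seed drives per-patient
  `SeedSequence` substreams, so enlarging `n_patients` leaves earlier
  patients' records byte-identical.

What the generator does **not** emulate — correlated comorbidities,
disease progression, informative testing, hospital clustering, dose and
adherence — bounds what the validation shows: passing tests demonstrate
that the pipeline recovers known parameters from data satisfying its own
assumptions, not that those assumptions hold in any real database.

Because events are detected only at the next test day and events occurring
within roughly one test interval of the censoring horizon can be missed,
recovered rate ratios carry a small attenuation (a few percent at the
default cadence); the parameter-recovery check bounds the net effect.

## Validation problem sizes

The recovery experiment uses a two-arm configuration (40% SOF+Rib with the
injected ratio, 45% control, 15% non-users) at 2,000 simulated patients ×
200 replicates; equal regimen lengths in both arms keep the
detection-delay attenuation symmetric. The null (type-I error) experiment
uses the default all-ratios-1 configuration at 500 patients × 500
replicates. Oracle comparisons run on 1,000 random prescription sets and
500 random follow-up instances. These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands while keeping the whole
validation suite to a few minutes.

## Known limitations

- The exact conditional test is conservative at very small event counts;
  under the null its rejection rate at p < 0.01 is well below nominal.
- "Proportional" era construction for ASV/GZR is an interpretation (see
  above).
- Whether a pattern change censors on, or the day before, the new
  prescription is not determined by the design description; the day before
  is used.
- Diagnosis/procedure coding systems are abstracted to a small controlled
  vocabulary; every diagnosis row is treated as confirmed.
- The published cohort counts and per-pattern rates of the emulated study
  derive from a non-public database and are not reproduction targets;
  validation is property-based on synthetic data.
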