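# daakidney

Risk of decreased kidney function in new users of direct-acting antivirals
(DAAs) against hepatitis C, analysed as person-time incidence-rate ratios
across prescription patterns — a complete, tested pharmacoepidemiology
pipeline exercised on synthetic electronic health records.

## Who this is for

Hospital-claims/EHR safety studies of this design (new-user cohort, active
comparator, laboratory-defined outcome) are usually locked to a private
database. `daakidney` re-implements the full analysis as a reusable Python
package so that every rule — index-date definition, exclusion criteria,
drug-era construction, outcome detection, censoring, exact inference — is
explicit, unit-tested, and can be validated end to end against simulated
data with known ground truth.

## The analysis

**Cohort.** A patient's index date *t₀* is their first prescription of a
target DAA inside the study window (2009-01-01 to 2017-12-31). New users
must have recorded history starting ≥ 90 days before *t₀*. Six exclusion
criteria then restrict to patients with baseline eGFR ≥ 45 mL/min/1.73 m²
and no kidney-related risk factors (pre-index eGFR < 45; dialysis,
transplantation, CKD or renal failure; diabetes, heart failure or
hypertension; no kidney-function lab in the 90-day lookback; impermissible
multi-DAA dispensing at *t₀*; missing mandatory concomitant drugs).

**Exposure.** Ten prescription patterns defined by the anchor DAA(s) at
*t₀* plus concomitant drugs within ±30 days (e.g. telaprevir +
peginterferon alpha + ribavirin; daclatasvir + asunaprevir; …), with
ledipasvir/sofosbuvir (LDV/SOF) as the control. Time-at-risk is the drug
era: supply intervals stitched across gaps ≤ 28 days, plus a 7-day grace
period.

**Outcome.** Daily eGFR (recorded values, same-day means; otherwise
converted from serum creatinine with the Japanese GFR equation
eGFR = 194·sCRE⁻¹·⁰⁹⁴·age⁻⁰·²⁸⁷ (× 0.739 for women)) is mapped to the
ordered KDIGO categories (≥ 90, 60–89, 45–59, 30–44, 15–29, < 15). The
event is the first post-index day whose category falls ≥ 1 category
(sensitivity: ≥ 2) below the pre-index baseline; follow-up ends at the
first of outcome, treatment end, pattern change, or study end.

**Inference.** Per pattern: events / person-years (days/365.25), and the
incidence-rate ratio versus the control with the exact conditional
binomial test and Clopper–Pearson-inverted 95% CI, flagged at the study's
p < 0.01 criterion. Baseline tables use Wilcoxon rank-sum and Fisher's
exact tests, with small-cell masking (< 10 → "< 10", dependent percentages
→ "NA").

## Worked example

```python
from daakidney import KidneyRiskModel, SimulationConfig, simulate_dataset

config = SimulationConfig(n_patients=2000, seed=11)
config.rate_ratio_per_pattern.update({"P1": 6.0, "P3": 4.0})
dataset, truth = simulate_dataset(config)

results = KidneyRiskModel(dataset).fit()   # drop_threshold=1, exact CIs
print(results.summary())
```

which prints (abridged):

```
new users of target DAAs               1710
  - insufficient history (<90 d)        331
  ...
final analyzable cohort                 539

Incidence of decreased kidney function (per person-year)
pattern               label  n_patients  events  person_years  rate      IRR (95% CI)      p  significant
     P1 TVR + Peg-IFN + Rib          28      11          5.92 1.858 5.24 (2.15-12.41) 0.0001         True
     P2 SMV + Peg-IFN + Rib          62      12         14.98 0.801  2.26 (0.95-5.26) 0.0458        False
     P3           DCV + ASV         152      99         51.26 1.931 5.44 (3.09-10.31) 0.0000         True
     P5           SOF + Rib          97      12         24.53 0.489  1.38 (0.58-3.21) 0.4253        False
     P7             LDV/SOF         156      14         39.44 0.355     1 (reference)
     ...
```

The two patterns with injected rate ratios (P1, true IRR 6; P3, true
IRR 4) are recovered and flagged at p < 0.01; the null patterns are not. `results.rates`, `results.baseline`,
`results.follow_up` and `results.attrition` hold the underlying tables;
`results.summary(masked=True)` applies the publication masking rule, and
`results.plot_rates()` draws the IRR forest plot.

The same pipeline is scriptable from a shell:

```bash
daakidney simulate --n 2000 --seed 7 --out-dir data/
daakidney run --data-dir data/ --out-dir results/ --drop-threshold 1
```

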