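# Methods

This note documents the models, decision rules and numerical choices
behind `stepscreen`, and what its synthetic-data tests do and do not
establish about real screening data.

## Instruments and severity bands

All three instruments are scored as simple item sums; no proration or
imputation rule exists, and incomplete questionnaires are rejected with
the offending item index. This is deliberate: the engine's downstream
logic operates entirely on severity bands, and silently prorating a
missing item could move a patient across a band boundary invisibly.

Band cutoffs (inclusive upper bounds) are configuration, with defaults

| instrument | nil-minimal | mild | moderate | severe |
|---|---|---|---|---|
| PHQ-9 | 0–4 | 5–9 | 10–19 | 20–27 |
| GAD-7 | 0–4 | 5–9 | 10–14 | 15–21 |

The PHQ-9 moderate band deliberately spans 10–19, merging the
conventional "moderate" and "moderately severe" bands into one stratum;
the conventional five-band PHQ-9 scheme is *not* used. AUDIT totals are
carried through without a band — risk-zone interpretation is left to the
GP. AUDIT items 1–8 accept 0–4 and items 9–10 only 0/2/4, per the
instrument's standard response sets.

Suicidal ideation is the raw PHQ-9 item-9 response (0–3 mapped to
none/mild/moderate/severe). It enables the GP support material at any
level ≥1 and is otherwise orthogonal to the severity pipeline: a property
test verifies that moving item 9 while compensating other items (total
held fixed) never changes the recommended step.

## Triage policy

Screen-positive means mild-or-worse on either instrument. Two
instruments are screened but patients are stratified into a single
severity group; the combination rule is `max(phq_band, gad_band)`. The
max rule is the natural stepped-care policy (escalate on the worst
presenting problem) and is the only simple rule consistent with severe
strata being overwhelmingly comorbid; it is nonetheless exposed as a
configurable policy (`severity_policy`), with a PHQ-9-priority variant
available for sensitivity analyses. Suicidal ideation with both bands
nil-minimal does not make a patient screen-positive — it enables the
supports only.

Step mapping: mild → Step 1 {web self-help}; moderate → Step 2 {guided
web therapy, psychologist, consider-medication}; severe → Step 3
{psychologist, medication, consider-psychiatrist}. Step 2's "guided web
therapy or psychologist" is emitted as a set of alternatives; the GP's
actual choice is a separate prescribing record, mirroring the
recommended-versus-prescribed distinction in the analytics. When
concordance tables are built, a "consider X" recommendation is counted as
a recommendation of X, which is how the recommended-category totals in
the study's tables are constructed (medication recommended for all
moderate and severe patients, psychiatrist for all severe patients).

Eligibility is the conjunction: age ≥18, not screened in the past 6
months, and a contact detail present.

## Monitoring

Baseline is week 0; follow-ups are scheduled at weeks 2, 4, …, 18 (nine
fortnights) for screen-positive patients only. Calendar dates are
abstracted to week numbers. Alert logic depends only on bands, never raw
totals (verified by perturbation tests).

* **Reference fortnight.** Improvement/deterioration compare the current
  completed assessment with the most recent *completed* assessment, or
  baseline when none exists (in particular at week 2). Comparing against
  a missed fortnight is undefined; carrying the last observation keeps
  the alert computable and conservative.
* **Severe-unchanging.** Evaluated per instrument: an instrument severe
  at baseline must itself have improved by ≥1 band at a completed week-2
  or week-4 assessment. If both early assessments are missed, the
  non-adherence alert (not this one) fires. The condition is frozen at
  week 4, so once true it holds at later evaluation weeks as well —
  downstream consumers typically act on its first occurrence.
* **Non-adherence.** Raised at week w exactly when the scheduled
  assessments at w and w−2 are both missed; a new pair re-raises it.
* **Opt-out** truncates the schedule: weeks after the opt-out week are
  neither scheduled nor counted toward non-adherence.

Completer outcome classes are judged at the last completed follow-up:
remitter = both instruments nil-minimal; responder = ≥1-band drop on
either instrument vs baseline; worsened = ≥1-band rise. Whether
"worsened" should instead mean *at any point during follow-up* is
ambiguous in measurement-based-care practice; the default is
last-assessment, with the any-point variant behind
`classify_worsened(..., at_any_point=True)` /
`EngineConfig.worsened_at_any_point`. Patients with no completed
follow-up are excluded from all completer analyses (complete-case, no
imputation).

## Cohort analytics

Every proportion retains its numerator/denominator pair; percentages are
rendered half-up at presentation only (2 dp for cohort proportions, 1 dp
for table cells), with full precision kept internally.

**NNS.** The absolute risk of new identification under screening is
AR = k/N over the *offered* denominator; the no-screening counterfactual
contributes AR = 0, so ARD = AR and NNS = 1/ARD. The CI is computed on
the risk scale and inverted (bounds swap under the reciprocal). The
default risk-scale interval is Wald, implemented via
`statsmodels.stats.proportion.proportion_confint(method="normal")`; this
choice is *inferred from numerical agreement* with the published interval
(Wald inversion reproduces 13.9–17.1 at k=335, N=5138, where Wilson gives
13.8) — the original analysis did not name its interval. Wilson is
available behind `ci_method="wilson"`. A degenerate k=0 has no defined
NNS and raises.

**Concordance.** Treatment categories are not mutually exclusive, and
prescribing/use surveys are optional, so denominators shift with data
availability: recommended rates are over all symptomatic patients,
prescribed rates over the prescribing-data subset, uptake over patients
with both prescribing and use data, conditioned on a prescription of the
grouping (digital = web self-help ∪ guided web therapy; high-intensity =
psychologist ∪ medication ∪ psychiatrist). Aggregate recommended rates
are reported over the prescribing subset so recommended and prescribed
shares share a denominator. Missing data are handled solely by these
complete-case denominators.

**Effect sizes.** d = |mean change| / baseline SD, for externally
supplied (mean change, SD) pairs. The longitudinal mixed model that
produces the mean changes is out of scope (it requires patient-level raw
data); only the effect-size arithmetic is implemented.

## Reference cohort

`stepscreen.reference` rebuilds the published study cohort from its
printed count tables: 5138 offered, 3777 completed, 3314 eligible, 1428
screen-positive (458 mild / 586 moderate / 384 severe), 454 with
suicidal ideation, 335 previously unidentified; a 334-patient prescribing
subset whose per-category and union counts match the printed prescribing
tables; 606 with use data (165 with both; digital uptake 35/52,
high-intensity 96/102); and 708 completers yielding 185 remitters, 392
responders and 185 worsened. Patient-level detail beyond what those
counts pin down (exact totals within a band, item patterns) is chosen
canonically and does not affect any band-level statistic. The printed
comorbidity breakdowns sum slightly short of their band totals (449 of
458 mild, 579 of 586 moderate, 382 of 384 severe); the residuals are
filled as depression-only, leaving every other margin exact.

## Simulator

The generator draws each offered patient through the cascade
completed → eligible → positive → overall band → (depression-only /
anxiety-only / comorbid) → suicidality → prior-identification, then GP
prescribing (per band × category), patient use (uptake given a
prescription of the grouping, background use otherwise) and a follow-up
timeline. Default probabilities are the study cohort's observed rates
(e.g. positivity 0.4309, severity mixture 458:586:384, unidentified
fraction 0.2346, prescribing-table frequencies), so a default run
resembles the study cohort; every field is configurable.

Item vectors are drawn uniformly over compositions of a sampled total
subject to per-item caps (exact uniformity via a dynamic-programming
count table), with PHQ-9 item 9 pinned to the drawn suicidality level and
the remaining items composing the balance; totals above item9+24 are
infeasible for the other eight items, so the total is sampled within the
feasible sub-range of its band. An IRT model was considered and rejected:
the engine consumes only totals and bands, so item-level realism beyond
range-validity would buy nothing.

Trajectories are linear in fortnights: s_j = s_0 + b·j + ε_j with
b ~ N(slope_mean, slope_sd²) per patient and ε_j ~ N(0, noise_sd²) per
occasion, truncated to the instrument range and rounded. Defaults:
slope means −3.62/9 (PHQ-9) and −1.45/9 (GAD-7) points per fortnight —
the study's modelled 18-week mean changes spread evenly over nine
fortnights — with slope SDs 0.6/0.4 and occasion noise SDs 2.0/1.8 points
chosen as realistic between-patient heterogeneity and short-term
measurement noise for these instruments. Missingness: a never-engage
probability of 1 − 708/1428 ≈ 0.504 reproduces the study's observed
completer fraction; engagers face a per-fortnight dropout hazard of 0.12
(from the second fortnight), intermittent misses at 0.12, and an opt-out
hazard of 0.02 per fortnight. Dropout is non-informative by default; a
severity-dependent hazard can be emulated by configuring band-specific
runs.

Everything derives from a single integer seed; identical (config, seed)
pairs regenerate identical cohorts, which tests assert by object
equality.

`parameter_recovery_report` replicates the full pipeline and compares
recovered rates to their config-implied truths: detection rate
(p_positive), unidentified fraction (p_unidentified·given positive), and
NNS, whose identification risk is the cascade product
p_complete·p_eligible·p_positive·p_unidentified. Remission and response
have no closed form under the trajectory model; the acceptance suite
checks them against an independent vectorised re-derivation of the
declared generative model instead.

## What the synthetic tests do and do not show

The simulator emulates the *statistical structure* the engine assumes:
cascade attrition, band mixtures, comorbidity rising with severity,
missingness patterns and band-scale symptom drift. It does not emulate
item-level response psychology (no IRT), informative dropout tied to
symptom level (off by default), practice-level clustering, seasonal or
calendar effects, or measurement reactivity. Passing tests therefore
demonstrate that the decision rules and statistics are implemented
correctly and recover known truths under the assumed structure — not that
the assumed structure matches any particular clinic's population.

## Numerical and scale choices

Percentage rounding is half-up via `decimal` (Python's built-in `round`
is banker's). The Wald coverage check runs at the study's operating point
(risk ≈ 0.065, n = 5000) with 1500 replicates; the full-engine parameter
recovery runs 40 replicates at the study's offered size (n = 5138), with
all Monte-Carlo comparisons at ±3 SE. The test suite and acceptance
script complete in a few minutes on one CPU at these sizes.

## Known limitations

* The severity-combination rule and the week-2 alert reference are
  policies the engine fixes by configuration; deployed screening tools
  vary on both and no published rule exists to copy.
* The NNS interval method is inferred (see above), not documented by the
  original analysis.
* Remission/response truths for the simulator are themselves Monte-Carlo
  estimates; their acceptance comparison carries both error terms.
* The engine validates single records eagerly; batch CSV ingestion
  collects row-level errors but does not attempt repair.
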