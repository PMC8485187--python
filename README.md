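# stepscreen

Mental-health screening, stepped-care triage, fortnightly symptom
monitoring and cohort analytics for general practice.

## The problem

Depression and anxiety are common in general-practice waiting rooms, but
only about half of affected patients are recognised by their GP.
Waiting-room screening with brief validated instruments, followed by a
severity-matched ("stepped care") treatment recommendation, can surface
previously unidentified patients — many of whom have mild-to-moderate
symptoms and are good candidates for low-intensity digital interventions.
`stepscreen` implements the full decision engine behind such a screening
programme, plus the statistics used to evaluate one, and a synthetic
cohort simulator so the whole pipeline can be exercised without any real
patient data.

## What the engine does

**Scoring and banding.** The PHQ-9 (9 items, 0–3 each, total 0–27) and
GAD-7 (7 items, total 0–21) are scored as item sums and mapped onto four
severity bands — PHQ-9: nil-minimal 0–4, mild 5–9, moderate 10–19, severe
20–27; GAD-7: nil-minimal 0–4, mild 5–9, moderate 10–14, severe 15–21.
The AUDIT (10 items, total 0–40) is scored and passed through unbanded.
PHQ-9 item 9 grades suicidal ideation (0 none / 1 mild / 2 moderate /
3 severe) and is reported in its own column, alongside — never inside —
the severity logic.

**Triage.** A patient screens positive when either instrument reaches the
mild band. Overall severity is the worse of the two bands and maps onto
treatment steps: mild → Step 1 (web-based self-help); moderate → Step 2
(guided web therapy or a psychologist, consider medication); severe →
Step 3 (psychologist plus medication, consider a psychiatrist). Any
ideation on item 9 switches on four GP supports (discussion prompts, risk
assessment, safety planning, crisis links). A positive patient with no
prior or current GP mental-health contact is flagged *previously
unidentified*.

**Monitoring.** Screen-positive patients are reassessed every 2 weeks for
18 weeks. Each follow-up can raise four GP alerts: improvement or
deterioration (±1 band on either instrument versus the most recent
completed assessment), severe-and-unchanging (a baseline-severe
instrument not improved by week 4), and non-adherence (two consecutive
missed assessments). Completers are classified at their last completed
follow-up: *remitters* (both instruments nil-minimal), *responders* (≥1
band drop on either instrument vs baseline), *worsened* (≥1 band rise).

**Cohort analytics.** Detection and severity distributions with their
count pairs, recommendation/prescribing/use concordance tables with
complete-case denominators, remission/response rates, standardised effect
sizes d = |Δ|/SD_baseline, and the number needed to screen

    AR_screening = k / N,   ARD = AR_screening − AR_no-screening,   NNS = 1 / ARD

under the counterfactual that no screening identifies nobody new
(AR_no-screening = 0). The NNS confidence interval is a Wald interval on
the risk scale, inverted onto the NNS scale (Wilson available as an
alternative).

**Simulator.** A configurable generator draws patients through the
offered → completed → eligible → positive → severity → comorbidity
cascade, composes item-level responses that re-score to the sampled
totals exactly, and produces fortnightly trajectories from a latent
linear model with patient-level slopes, occasion noise, informative-free
dropout, intermittent misses and opt-out. Defaults mirror the Australian
general-practice cohort the engine was developed around (N=5138 offered).

## Worked example

```python
from stepscreen import Instrument, ItemResponses, ScreeningRecord, triage

record = ScreeningRecord(
    patient_id="example-001", age=43, sex="F",
    contact_detail_present=True, screened_within_6_months=False,
    prior_gp_mh_contact=False, current_visit_mh=False,
    phq9=ItemResponses(Instrument.PHQ9, (2, 2, 1, 2, 1, 1, 1, 1, 1)),
    gad7=ItemResponses(Instrument.GAD7, (1, 1, 1, 1, 1, 1, 0)),
    audit=ItemResponses(Instrument.AUDIT, (1, 1, 1, 0, 0, 0, 0, 0, 0, 0)),
)
result = triage(record)
```

prints (via `python examples/01_score_and_triage.py`):

```
PHQ-9 total 12 -> MODERATE
GAD-7 total 6 -> MILD
overall severity: MODERATE
recommended step: STEP2
recommended treatments: ['GUIDED_WEB_THERAPY', 'MEDICATION_CONSIDER', 'PSYCHOLOGIST']
suicidality: MILD - GP supports enabled: True
previously unidentified: True
```

The PHQ-9 total of 12 falls in the moderate band, which dominates the
mild GAD-7 band, so the patient is recommended Step 2; the item-9
response of 1 enables the GP's suicidality support material without
changing the step.

At cohort level (`python examples/03_cohort_statistics.py`):

```
detection rate: 1428/3314 = 43.09%
number needed to screen: 15.3 (95% CI 13.9-17.1)
completers n=708: remitters 26.1%, responders 55.4%, worsened 26.1%
```

i.e. 43% of eligible patients screened positive, one previously
unidentified symptomatic patient is found per ~16 patients offered
screening, and a quarter of monitored completers reached the
asymptomatic range on both instruments.

Other example scripts cover the monitoring alerts
(`examples/02_monitoring_alerts.py`) and the simulator with parameter
recovery (`examples/04_simulate_and_recover.py`). A thin CLI wraps the
same pipelines: `stepscreen simulate | score | triage | monitor |
cohort-stats | nns | recover` (see `stepscreen --help`).

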