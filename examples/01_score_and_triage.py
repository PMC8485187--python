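"""Score one patient's questionnaires and run the stepped-care triage.

A 43-year-old with moderate depressive symptoms (PHQ-9 total 12, some
suicidal ideation on item 9) and mild anxiety (GAD-7 total 6) who has
never raised mental health with their GP.
"""

from stepscreen import (
    Instrument,
    ItemResponses,
    ScreeningRecord,
    check_eligibility,
    triage,
)

record = ScreeningRecord(
    patient_id="example-001",
    age=43,
    sex="F",
    contact_detail_present=True,
    screened_within_6_months=False,
    prior_gp_mh_contact=False,
    current_visit_mh=False,
    phq9=ItemResponses(Instrument.PHQ9, (2, 2, 1, 2, 1, 1, 1, 1, 1)),
    gad7=ItemResponses(Instrument.GAD7, (1, 1, 1, 1, 1, 1, 0)),
    audit=ItemResponses(Instrument.AUDIT, (1, 1, 1, 0, 0, 0, 0, 0, 0, 0)),
)

print("eligible for screening:", check_eligibility(record))
result = triage(record)
print(f"PHQ-9 total {result.phq_score.total} -> {result.phq_band.name}")
print(f"GAD-7 total {result.gad_score.total} -> {result.gad_band.name}")
print(f"AUDIT total {result.audit_score.total} (passed to the GP unbanded)")
print("overall severity:", result.overall_band.name)
print("recommended step:", result.step.value)
print("recommended treatments:", sorted(t.value for t in result.recommended_treatments))
print("suicidality:", result.suicidality.name, "- GP supports enabled:", result.supports.any_enabled)
print("previously unidentified:", result.previously_unidentified)

# The overall band is the worse of the two instruments (here MODERATE from
# the PHQ-9), which maps to Step 2: guided web therapy or a psychologist,
# with medication to consider.  Item 9 = 1 switches on the GP's
# suicidality support material but never changes the step.
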