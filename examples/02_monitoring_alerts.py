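"""Follow a monitored patient through the 18-week fortnightly schedule.

The patient starts severe on the PHQ-9, misses week 6 and 8, and
improves from week 10.  The four GP alerts (improvement, deterioration,
severe-unchanging, non-adherence) are evaluated at each scheduled week.
"""

from stepscreen import FollowUpAssessment, PatientTimeline, build_schedule, detect_alerts, triage
from stepscreen.reference import gad7_items_for_total, phq9_items_for_total
from examples_common import make_baseline_record

baseline = triage(make_baseline_record(phq_total=22, gad_total=8))
print("schedule (weeks):", build_schedule(baseline))


def visit(week, phq=None, gad=None):
    done = phq is not None
    return FollowUpAssessment(
        week=week,
        completed=done,
        phq9=phq9_items_for_total(phq) if done else None,
        gad7=gad7_items_for_total(gad) if done else None,
    )


timeline = PatientTimeline(
    patient_id=baseline.patient_id,
    baseline=baseline,
    followups=(
        visit(2, 22, 8),   # still severe
        visit(4, 21, 8),   # still severe at week 4 -> severe-unchanging alert
        visit(6),          # missed
        visit(8),          # missed -> non-adherence alert
        visit(10, 14, 6),  # moderate now -> improvement vs last completed (week 4)
        visit(12, 8, 4),   # mild
    ),
)

for week in (2, 4, 6, 8, 10, 12):
    a = detect_alerts(timeline, week)
    flags = [
        name
        for name, on in [
            ("improvement", a.improvement),
            ("deterioration", a.deterioration),
            ("severe-unchanging", a.severe_unchanging),
            ("non-adherence", a.nonadherent),
        ]
        if on
    ]
    print(f"week {week:2d}: {', '.join(flags) if flags else 'no alerts'}")

# Band comparisons always use the most recent completed assessment as the
# reference, so the week-10 improvement is judged against week 4, not the
# missed week 8.
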