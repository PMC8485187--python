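"""Cohort-level analytics over the published study's count tables.

The reference module rebuilds the study cohort (5138 offered, 3314
eligible, 1428 screen-positive) from its printed counts; the analytics
recover every published rate, including the number needed to screen.
"""

from stepscreen import (
    SeverityBand,
    cohen_d,
    concordance,
    nns,
    remission_response_rates,
    summarize_cohort,
)
from stepscreen.reference import (
    COUNTS,
    reference_timelines,
    reference_treatment_records,
    reference_triage_results,
)

summary = summarize_cohort(reference_triage_results(), COUNTS["n_offered"], COUNTS["n_completed"])
print(f"detection rate: {summary.detection_rate} = {summary.detection_rate.pct()}%")
for band in (SeverityBand.MILD, SeverityBand.MODERATE, SeverityBand.SEVERE):
    p = summary.band_rates[band]
    print(f"  {band.name.lower():9s}: {p} = {p.pct()}%")
print(f"suicidal ideation (symptomatic sample): {summary.suicidal_rate.pct()}%")
print(f"previously unidentified: {summary.unidentified_rate.pct()}%")

r = nns(summary.n_unidentified, summary.n_offered)
print(f"number needed to screen: {r.formatted()}")
print("  (one newly identified symptomatic patient per ~16 offered screening)")

table = concordance(reference_treatment_records())
print(
    f"digital interventions: recommended {table.recommended_digital.pct(1)}%, "
    f"prescribed {table.prescribed_digital.pct(1)}%, "
    f"uptake when prescribed {table.uptake_digital.pct(0)}%"
)
print(
    f"high-intensity: recommended {table.recommended_high_intensity.pct(1)}%, "
    f"prescribed {table.prescribed_high_intensity.pct(1)}%, "
    f"uptake {table.uptake_high_intensity.pct(1)}%"
)

rates = remission_response_rates(reference_timelines())
print(
    f"completers n={rates.n_completers}: remitters {rates.remitter_rate.pct(1)}%, "
    f"responders {rates.responder_rate.pct(1)}%, worsened {rates.worsened_rate.pct(1)}%"
)

cp, sp = COUNTS["phq_change_sd"]
cg, sg = COUNTS["gad_change_sd"]
print(f"18-week effect sizes: PHQ-9 d={cohen_d(cp, sp):.2f}, GAD-7 d={cohen_d(cg, sg):.2f}")
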