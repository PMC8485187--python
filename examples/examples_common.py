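"""Shared helper for the example scripts."""

from stepscreen import Instrument, ItemResponses, ScreeningRecord
from stepscreen.reference import gad7_items_for_total, phq9_items_for_total


def make_baseline_record(phq_total: int, gad_total: int, pid: str = "example-002") -> ScreeningRecord:
    return ScreeningRecord(
        patient_id=pid,
        age=38,
        sex="M",
        contact_detail_present=True,
        screened_within_6_months=False,
        prior_gp_mh_contact=True,
        current_visit_mh=False,
        phq9=phq9_items_for_total(phq_total),
        gad7=gad7_items_for_total(gad_total),
        audit=ItemResponses(Instrument.AUDIT, (0,) * 10),
    )
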