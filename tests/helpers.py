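"""Shared constructors for tests: minimal records and timelines."""

from __future__ import annotations

from stepscreen import (
    FollowUpAssessment,
    Instrument,
    ItemResponses,
    PatientTimeline,
    ScreeningRecord,
    triage,
)
from stepscreen.reference import gad7_items_for_total, phq9_items_for_total

AUDIT_ZERO = ItemResponses(Instrument.AUDIT, (0,) * 10)


def make_record(
    phq_total: int = 0,
    gad_total: int = 0,
    item9: int = 0,
    age: float = 43.0,
    prior: bool = False,
    current: bool = False,
    contact: bool = True,
    screened_recently: bool = False,
    pid: str = "p1",
) -> ScreeningRecord:
    return ScreeningRecord(
        patient_id=pid,
        age=age,
        sex="F",
        contact_detail_present=contact,
        screened_within_6_months=screened_recently,
        prior_gp_mh_contact=prior,
        current_visit_mh=current,
        phq9=phq9_items_for_total(phq_total, item9),
        gad7=gad7_items_for_total(gad_total),
        audit=AUDIT_ZERO,
    )


def make_timeline(
    phq0: int,
    gad0: int,
    followups: list[tuple[int, int | None, int | None]],
    opted_out_week: int | None = None,
    pid: str = "p1",
) -> PatientTimeline:
    """Followups are (week, phq_total, gad_total); None totals mean missed."""
    baseline = triage(make_record(phq0, gad0, pid=pid))
    fu = tuple(
        FollowUpAssessment(
            week=w,
            completed=pt is not None,
            phq9=phq9_items_for_total(pt) if pt is not None else None,
            gad7=gad7_items_for_total(gt) if gt is not None else None,
        )
        for w, pt, gt in followups
    )
    return PatientTimeline(
        patient_id=pid, baseline=baseline, followups=fu, opted_out_week=opted_out_week
    )


# Representative total inside each band, per instrument.
PHQ_BAND_TOTAL = {0: 2, 1: 7, 2: 12, 3: 22}
GAD_BAND_TOTAL = {0: 2, 1: 7, 2: 12, 3: 16}
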