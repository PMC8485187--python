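"""Baseline triage: screen-positive status, overall severity, stepped-care
recommendation, suicidality supports, eligibility and prior-identification.

The engine screens two instruments but stratifies each patient into a
single severity group; the combination rule is the maximum of the two
bands (escalate on the worst instrument), exposed as a configurable
policy.  Suicidal ideation is flagged and enables GP support material but
never alters the treatment step — it travels in a separate column of the
screening report.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .bands import SeverityBand, SuicidalityLevel
from .instruments import (
    InstrumentScore,
    ItemResponses,
    grade_suicidality,
    score_audit,
    score_gad7,
    score_phq9,
)

__all__ = [
    "TreatmentStep",
    "Treatment",
    "ScreeningRecord",
    "TriageResult",
    "SuicidalitySupports",
    "check_eligibility",
    "screen_positive",
    "overall_severity",
    "recommend_step",
    "suicidality_supports",
    "classify_previously_unidentified",
    "triage",
    "STEP_TREATMENTS",
]


class TreatmentStep(str, Enum):
    NONE = "NONE"
    STEP1 = "STEP1"
    STEP2 = "STEP2"
    STEP3 = "STEP3"


class Treatment(str, Enum):
    WEB_SELF_HELP = "WEB_SELF_HELP"
    GUIDED_WEB_THERAPY = "GUIDED_WEB_THERAPY"
    PSYCHOLOGIST = "PSYCHOLOGIST"
    MEDICATION_CONSIDER = "MEDICATION_CONSIDER"
    MEDICATION = "MEDICATION"
    PSYCHIATRIST_CONSIDER = "PSYCHIATRIST_CONSIDER"
    PSYCHIATRIST = "PSYCHIATRIST"  # GP-prescribed category; never tool-recommended


# Step 2 offers guided web therapy OR a psychologist (GP chooses), with
# medication to consider; step 3 is psychologist plus medication, with a
# psychiatrist to consider.
STEP_TREATMENTS: dict[TreatmentStep, frozenset[Treatment]] = {
    TreatmentStep.NONE: frozenset(),
    TreatmentStep.STEP1: frozenset({Treatment.WEB_SELF_HELP}),
    TreatmentStep.STEP2: frozenset(
        {Treatment.GUIDED_WEB_THERAPY, Treatment.PSYCHOLOGIST, Treatment.MEDICATION_CONSIDER}
    ),
    TreatmentStep.STEP3: frozenset(
        {Treatment.PSYCHOLOGIST, Treatment.MEDICATION, Treatment.PSYCHIATRIST_CONSIDER}
    ),
}

_BAND_TO_STEP = {
    SeverityBand.NIL_MINIMAL: TreatmentStep.NONE,
    SeverityBand.MILD: TreatmentStep.STEP1,
    SeverityBand.MODERATE: TreatmentStep.STEP2,
    SeverityBand.SEVERE: TreatmentStep.STEP3,
}


@dataclass(frozen=True)
class ScreeningRecord:
    """One patient's baseline questionnaire, demographics and contact flags."""

    patient_id: str
    age: float
    sex: str
    contact_detail_present: bool
    screened_within_6_months: bool
    prior_gp_mh_contact: bool
    current_visit_mh: bool
    phq9: ItemResponses
    gad7: ItemResponses
    audit: ItemResponses
    carer: bool = False
    language_other_than_english: bool = False
    housing_concerns: bool = False
    aboriginal_torres_strait_islander: bool = False

    def __post_init__(self):
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")


@dataclass(frozen=True)
class SuicidalitySupports:
    """GP support material enabled when any suicidal ideation is reported."""

    discussion_prompts: bool
    risk_assessment_steps: bool
    safety_plan_guidance: bool
    crisis_links: bool

    @property
    def any_enabled(self) -> bool:
        return self.discussion_prompts


@dataclass(frozen=True)
class TriageResult:
    """The full triage outcome for one screened patient."""

    patient_id: str
    phq_score: InstrumentScore
    gad_score: InstrumentScore
    audit_score: InstrumentScore
    phq_band: SeverityBand
    gad_band: SeverityBand
    overall_band: SeverityBand
    screen_positive: bool
    suicidality: SuicidalityLevel
    supports: SuicidalitySupports
    step: TreatmentStep
    recommended_treatments: frozenset[Treatment]
    previously_unidentified: bool


def check_eligibility(record: ScreeningRecord) -> bool:
    """Adults not screened in the past 6 months who left a contact detail."""
    return (
        record.age >= 18
        and not record.screened_within_6_months
        and record.contact_detail_present
    )


def screen_positive(phq_band: SeverityBand, gad_band: SeverityBand) -> bool:
    """Positive screen: mild-or-worse band on either instrument."""
    return phq_band >= SeverityBand.MILD or gad_band >= SeverityBand.MILD


def overall_severity(
    phq_band: SeverityBand, gad_band: SeverityBand, policy: str = "max"
) -> SeverityBand:
    """Combine the two instrument bands into one stratum.

    ``max`` (default) escalates on the worse instrument; ``phq_priority``
    uses the depression band alone unless it is nil-minimal.
    """
    if policy == "max":
        return max(phq_band, gad_band)
    if policy == "phq_priority":
        return phq_band if phq_band > SeverityBand.NIL_MINIMAL else gad_band
    raise ValueError(f"unknown severity-combination policy {policy!r}")


def recommend_step(overall: SeverityBand) -> tuple[TreatmentStep, frozenset[Treatment]]:
    """Map the overall severity band to a stepped-care recommendation."""
    step = _BAND_TO_STEP[overall]
    return step, STEP_TREATMENTS[step]


def suicidality_supports(level: SuicidalityLevel) -> SuicidalitySupports:
    """All four GP supports switch on together for any ideation (level >= 1)."""
    on = level >= SuicidalityLevel.MILD
    return SuicidalitySupports(on, on, on, on)


def classify_previously_unidentified(record: ScreeningRecord, positive: bool) -> bool:
    """Screen-positive with no prior or current GP mental-health contact."""
    return positive and not record.prior_gp_mh_contact and not record.current_visit_mh


def triage(
    record: ScreeningRecord,
    severity_policy: str = "max",
    phq_cutoffs=None,
    gad_cutoffs=None,
) -> TriageResult:
    """Run the full baseline triage for one patient.

    Pure and deterministic: scoring, banding, screen-positive status,
    severity combination, step recommendation, suicidality grading and
    prior-identification status, composed in order.  Band cutoffs default
    to the standard scheme; alternative :class:`~stepscreen.bands.BandCutoffs`
    support sensitivity analyses without code change.
    """
    from .bands import GAD7_CUTOFFS, PHQ9_CUTOFFS

    phq = score_phq9(record.phq9, phq_cutoffs or PHQ9_CUTOFFS)
    gad = score_gad7(record.gad7, gad_cutoffs or GAD7_CUTOFFS)
    aud = score_audit(record.audit)
    positive = screen_positive(phq.band, gad.band)
    overall = overall_severity(phq.band, gad.band, severity_policy)
    step, treatments = recommend_step(overall)
    level = grade_suicidality(record.phq9.items[8])
    return TriageResult(
        patient_id=record.patient_id,
        phq_score=phq,
        gad_score=gad,
        audit_score=aud,
        phq_band=phq.band,
        gad_band=gad.band,
        overall_band=overall,
        screen_positive=positive,
        suicidality=level,
        supports=suicidality_supports(level),
        step=step,
        recommended_treatments=treatments,
        previously_unidentified=classify_previously_unidentified(record, positive),
    )
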