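"""Fortnightly follow-up monitoring: schedule, GP alerts, outcome classes.

Screen-positive patients are re-assessed every 2 weeks for 18 weeks
(weeks 2, 4, ..., 18; baseline is week 0).  Each completed follow-up can
raise four GP alerts:

* improvement — either instrument dropped at least one severity band
  versus the reference fortnight;
* deterioration — either instrument rose at least one band versus the
  reference fortnight;
* severe & unchanging — an instrument severe at baseline has not improved
  by at least one band by week 4;
* non-adherence — the two most recent scheduled assessments were both
  missed.

The reference fortnight is the most recent *completed* assessment (or
baseline when none exists — in particular at week 2): comparing against a
missed assessment is undefined, so the last observation is carried as the
comparison point.

Completer outcome classes (remitter / responder / worsened) are judged at
the last completed follow-up; patients with no completed follow-up are
excluded from completer analyses.  All alert and outcome logic operates on
severity bands, never raw totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bands import SeverityBand
from .errors import NonCompleterError, ScheduleError
from .instruments import ItemResponses, score_gad7, score_phq9
from .triage import TriageResult

__all__ = [
    "SCHEDULE_WEEKS",
    "FollowUpAssessment",
    "PatientTimeline",
    "AlertSet",
    "build_schedule",
    "detect_alerts",
    "last_assessment",
    "classify_remitter",
    "classify_responder",
    "classify_worsened",
]

SCHEDULE_WEEKS: tuple[int, ...] = tuple(range(2, 20, 2))


@dataclass(frozen=True)
class FollowUpAssessment:
    """One scheduled fortnightly assessment, completed or missed.

    ``phq9``/``gad7`` are present iff ``completed``; bands are derived at
    construction so downstream logic never re-scores.
    """

    week: int
    completed: bool
    phq9: ItemResponses | None = None
    gad7: ItemResponses | None = None
    phq_band: SeverityBand | None = field(default=None, init=False)
    gad_band: SeverityBand | None = field(default=None, init=False)

    def __post_init__(self):
        if self.week not in SCHEDULE_WEEKS:
            raise ScheduleError(f"week {self.week} is not a scheduled fortnight")
        if self.completed:
            if self.phq9 is None or self.gad7 is None:
                raise ValueError(f"completed assessment at week {self.week} lacks scores")
            object.__setattr__(self, "phq_band", score_phq9(self.phq9).band)
            object.__setattr__(self, "gad_band", score_gad7(self.gad7).band)
        else:
            if self.phq9 is not None or self.gad7 is not None:
                raise ValueError(f"missed assessment at week {self.week} carries scores")


@dataclass(frozen=True)
class PatientTimeline:
    """Baseline triage plus the ordered fortnightly follow-ups for one patient."""

    patient_id: str
    baseline: TriageResult
    followups: tuple[FollowUpAssessment, ...]
    opted_out_week: int | None = None

    def __post_init__(self):
        if not self.baseline.screen_positive:
            raise ScheduleError(
                f"patient {self.patient_id} screened negative; nil-minimal patients "
                "are not followed up"
            )
        weeks = [f.week for f in self.followups]
        if weeks != sorted(set(weeks)):
            raise ValueError(f"follow-up weeks must be strictly increasing, got {weeks}")
        if self.opted_out_week is not None:
            late = [w for w in weeks if w > self.opted_out_week]
            if late:
                raise ValueError(
                    f"assessments {late} fall after opt-out week {self.opted_out_week}"
                )

    def scheduled_weeks(self) -> tuple[int, ...]:
        """Scheduled weeks, truncated at opt-out."""
        if self.opted_out_week is None:
            return SCHEDULE_WEEKS
        return tuple(w for w in SCHEDULE_WEEKS if w <= self.opted_out_week)

    def assessment_at(self, week: int) -> FollowUpAssessment | None:
        for f in self.followups:
            if f.week == week:
                return f
        return None

    def completed_followups(self) -> tuple[FollowUpAssessment, ...]:
        return tuple(f for f in self.followups if f.completed)

    def baseline_bands(self) -> tuple[SeverityBand, SeverityBand]:
        return self.baseline.phq_band, self.baseline.gad_band


@dataclass(frozen=True)
class AlertSet:
    """The GP alerts raised for one patient at one scheduled week."""

    week: int
    improvement: bool
    deterioration: bool
    severe_unchanging: bool
    nonadherent: bool

    @property
    def any(self) -> bool:
        return self.improvement or self.deterioration or self.severe_unchanging or self.nonadherent


def build_schedule(baseline: TriageResult) -> tuple[int, ...]:
    """The nine fortnightly assessment weeks for a screen-positive patient."""
    if not baseline.screen_positive:
        raise ScheduleError("screen-negative patients are not monitored")
    return SCHEDULE_WEEKS


def _reference_bands(
    timeline: PatientTimeline, week: int
) -> tuple[SeverityBand, SeverityBand]:
    """Bands at the most recent completed assessment before ``week``
    (baseline when none exists)."""
    ref = timeline.baseline_bands()
    for f in timeline.followups:
        if f.week >= week:
            break
        if f.completed:
            ref = (f.phq_band, f.gad_band)
    return ref


def _missed(timeline: PatientTimeline, week: int) -> bool:
    a = timeline.assessment_at(week)
    return a is None or not a.completed


def detect_alerts(timeline: PatientTimeline, week: int) -> AlertSet:
    """Evaluate the four GP alerts at a scheduled week.

    All assessments up to ``week`` must be recorded in the timeline
    (missed fortnights as ``completed=False`` entries or simply absent).
    """
    if week not in timeline.scheduled_weeks():
        raise ScheduleError(
            f"week {week} is not scheduled for patient {timeline.patient_id}"
        )

    current = timeline.assessment_at(week)
    improvement = deterioration = False
    if current is not None and current.completed:
        ref_phq, ref_gad = _reference_bands(timeline, week)
        improvement = current.phq_band < ref_phq or current.gad_band < ref_gad
        deterioration = current.phq_band > ref_phq or current.gad_band > ref_gad

    # Non-adherence: the two most recent scheduled assessments both missed.
    sched = [w for w in timeline.scheduled_weeks() if w <= week]
    nonadherent = len(sched) >= 2 and _missed(timeline, sched[-1]) and _missed(
        timeline, sched[-2]
    )

    severe_unchanging = False
    if week >= 4:
        early = [
            timeline.assessment_at(w)
            for w in (2, 4)
            if w in timeline.scheduled_weeks()
        ]
        early_completed = [a for a in early if a is not None and a.completed]
        if early_completed:  # both missed -> nonadherence covers it
            b_phq, b_gad = timeline.baseline_bands()
            for base_band, attr in ((b_phq, "phq_band"), (b_gad, "gad_band")):
                if base_band == SeverityBand.SEVERE and not any(
                    getattr(a, attr) < SeverityBand.SEVERE for a in early_completed
                ):
                    severe_unchanging = True
    return AlertSet(week, improvement, deterioration, severe_unchanging, nonadherent)


def last_assessment(timeline: PatientTimeline) -> FollowUpAssessment:
    """The completed follow-up with the greatest week number."""
    completed = timeline.completed_followups()
    if not completed:
        raise NonCompleterError(
            f"patient {timeline.patient_id} completed no follow-up assessment"
        )
    return completed[-1]


def is_completer(timeline: PatientTimeline) -> bool:
    return bool(timeline.completed_followups())


def classify_remitter(timeline: PatientTimeline) -> bool:
    """Nil-minimal on both instruments at the last completed follow-up."""
    last = last_assessment(timeline)
    return (
        last.phq_band == SeverityBand.NIL_MINIMAL
        and last.gad_band == SeverityBand.NIL_MINIMAL
    )


def classify_responder(timeline: PatientTimeline) -> bool:
    """Dropped at least one severity band on either instrument at the last
    follow-up versus baseline."""
    last = last_assessment(timeline)
    b_phq, b_gad = timeline.baseline_bands()
    return last.phq_band < b_phq or last.gad_band < b_gad


def classify_worsened(timeline: PatientTimeline, at_any_point: bool = False) -> bool:
    """Rose at least one severity band on either instrument versus baseline.

    By default the comparison is at the last completed follow-up; with
    ``at_any_point=True`` a rise at any completed follow-up counts.
    """
    b_phq, b_gad = timeline.baseline_bands()
    if at_any_point:
        completed = timeline.completed_followups()
        if not completed:
            raise NonCompleterError(
                f"patient {timeline.patient_id} completed no follow-up assessment"
            )
        return any(f.phq_band > b_phq or f.gad_band > b_gad for f in completed)
    last = last_assessment(timeline)
    return last.phq_band > b_phq or last.gad_band > b_gad
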