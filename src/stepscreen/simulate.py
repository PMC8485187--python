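"""Synthetic general-practice screening cohorts.

Generates patients through the full screening cascade — offered →
completed → eligible → screen-positive → severity/comorbidity →
suicidality → prior-identification — plus GP prescribing, patient
treatment use, and fortnightly follow-up timelines with informative-free
(default) dropout and intermittent missingness.  Default parameters
mirror the observed rates of the general-practice study cohort the engine
was built around, so a desk-scale run resembles that cohort; every field
is configurable.

Item-level responses are generated by uniform composition of a sampled
total (see :mod:`stepscreen._compose`): the engine consumes only totals
and bands, so item-level realism beyond range-validity buys nothing.  The
PHQ-9 item 9 is pinned to the drawn suicidality level and the remaining
eight items are composed to preserve the target total.

Latent symptom trajectories are linear per patient: for fortnight
``j = 1..9`` the latent total is ``s_j = s_0 + b * j + eps_j`` with a
patient-level slope ``b ~ N(slope_mean, slope_sd)`` and occasion noise
``eps_j ~ N(0, noise_sd)``, truncated to the instrument range and rounded
to an integer.  Missingness is monotone dropout (per-fortnight hazard)
plus independent intermittent misses; opt-out truncates the schedule.

Everything is driven by a single seed: identical (config, seed) pairs
regenerate identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

from ._compose import sample_composition
from .bands import GAD7_CUTOFFS, PHQ9_CUTOFFS, SeverityBand
from .instruments import Instrument, ItemResponses
from .monitoring import SCHEDULE_WEEKS, FollowUpAssessment, PatientTimeline
from .analytics import PatientTreatmentRecord
from .triage import ScreeningRecord, Treatment, TriageResult, triage

__all__ = [
    "TrajectoryParams",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_timeline",
    "parameter_recovery_report",
    "RecoveryReport",
]

_BANDS_POS = (SeverityBand.MILD, SeverityBand.MODERATE, SeverityBand.SEVERE)


class TrajectoryParams(BaseModel):
    """Latent linear symptom path for one instrument (units: score points)."""

    slope_mean: float  # mean change per fortnight
    slope_sd: float = Field(ge=0)
    noise_sd: float = Field(ge=0)


class SimulationConfig(BaseModel):
    """All knobs of the cohort generator.

    Probability defaults are the study cohort's observed rates; trajectory,
    dropout and uptake defaults are documented in the methods note.
    """

    n_offered: int = 5138
    p_complete: float = Field(default=3777 / 5138, ge=0, le=1)
    p_eligible: float = Field(default=3314 / 3777, ge=0, le=1)  # given completed
    p_positive: float = Field(default=1428 / 3314, ge=0, le=1)  # given eligible
    # Severity mixture over (mild, moderate, severe) given screen-positive.
    severity_mixture: tuple[float, float, float] = (458 / 1428, 586 / 1428, 384 / 1428)
    # Comorbidity composition (depression-only, anxiety-only, both) per band.
    comorbidity_given_band: dict[str, tuple[float, float, float]] = {
        "MILD": (346 / 449, 54 / 449, 49 / 449),
        "MODERATE": (202 / 579, 28 / 579, 349 / 579),
        "SEVERE": (7 / 382, 13 / 382, 362 / 382),
    }
    p_suicidal_given_positive: float = Field(default=454 / 1428, ge=0, le=1)
    suicidality_level_weights: tuple[float, float, float] = (0.60, 0.28, 0.12)
    p_unidentified_given_positive: float = Field(default=335 / 1428, ge=0, le=1)
    # Contact flags for identified (non-new) positives and for negatives.
    p_current_visit_mh_given_identified: float = Field(default=0.45, ge=0, le=1)
    p_prior_contact_given_identified: float = Field(default=0.85, ge=0, le=1)
    p_prior_contact_negative: float = Field(default=0.40, ge=0, le=1)
    p_current_visit_negative: float = Field(default=0.08, ge=0, le=1)
    # Data availability and GP prescribing per band x category.
    p_rx_data: float = Field(default=334 / 1428, ge=0, le=1)
    p_use_data: float = Field(default=606 / 1428, ge=0, le=1)
    gp_prescribe_probs: dict[str, dict[str, float]] = {
        "MILD": {
            "WEB_SELF_HELP": 33 / 101,
            "GUIDED_WEB_THERAPY": 11 / 101,
            "PSYCHOLOGIST": 22 / 101,
            "MEDICATION": 8 / 101,
            "PSYCHIATRIST": 2 / 101,
        },
        "MODERATE": {
            "WEB_SELF_HELP": 15 / 140,
            "GUIDED_WEB_THERAPY": 28 / 140,
            "PSYCHOLOGIST": 59 / 140,
            "MEDICATION": 50 / 140,
            "PSYCHIATRIST": 8 / 140,
        },
        "SEVERE": {
            "WEB_SELF_HELP": 12 / 93,
            "GUIDED_WEB_THERAPY": 15 / 93,
            "PSYCHOLOGIST": 54 / 93,
            "MEDICATION": 51 / 93,
            "PSYCHIATRIST": 21 / 93,
        },
    }
    # Patient uptake given a prescription of the grouping, and background
    # use without one.
    uptake_digital: float = Field(default=35 / 52, ge=0, le=1)
    uptake_high_intensity: float = Field(default=96 / 102, ge=0, le=1)
    background_use_digital: float = Field(default=0.15, ge=0, le=1)
    background_use_high_intensity: float = Field(default=0.55, ge=0, le=1)
    # Longitudinal model.
    phq_trajectory: TrajectoryParams = TrajectoryParams(
        slope_mean=-3.62 / 9, slope_sd=0.6, noise_sd=2.0
    )
    gad_trajectory: TrajectoryParams = TrajectoryParams(
        slope_mean=-1.45 / 9, slope_sd=0.4, noise_sd=1.8
    )
    # Roughly half of monitored patients never complete a single follow-up;
    # the rest are subject to a per-fortnight dropout hazard plus
    # intermittent misses.
    p_never_engage: float = Field(default=1 - 708 / 1428, ge=0, le=1)
    dropout_hazard: float = Field(default=0.12, ge=0, le=1)
    intermittent_miss: float = Field(default=0.12, ge=0, le=1)
    optout_hazard: float = Field(default=0.02, ge=0, le=1)
    # Demographics.
    age_mean: float = 43.4
    age_sd: float = 17.0
    p_female: float = Field(default=0.6989, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check_mixtures(self):
        if abs(sum(self.severity_mixture) - 1) > 1e-9:
            raise ValueError("severity_mixture must sum to 1")
        for band, mix in self.comorbidity_given_band.items():
            if abs(sum(mix) - 1) > 1e-9:
                raise ValueError(f"comorbidity mixture for {band} must sum to 1")
        return self


@dataclass(frozen=True)
class SyntheticCohort:
    """A fully generated cohort plus its generating provenance."""

    config: SimulationConfig
    seed: int
    n_offered: int
    n_completed: int
    n_eligible: int
    records: tuple[ScreeningRecord, ...]
    triage_results: tuple[TriageResult, ...]
    treatment_records: tuple[PatientTreatmentRecord, ...]
    timelines: tuple[PatientTimeline, ...]

    @property
    def n_positive(self) -> int:
        return sum(r.screen_positive for r in self.triage_results)

    @property
    def n_unidentified(self) -> int:
        return sum(r.previously_unidentified for r in self.triage_results)


def _sample_total(
    band: SeverityBand,
    cutoffs,
    rng: np.random.Generator,
    min_total: int = 0,
    max_total: int | None = None,
) -> int:
    lo, hi = cutoffs.band_range(band)
    lo = max(lo, min_total)
    if max_total is not None:
        hi = min(hi, max_total)
    if lo > hi:
        raise ValueError(f"no feasible total in band {band} within [{min_total}, {max_total}]")
    return int(rng.integers(lo, hi + 1))


def _phq_items(total: int, item9: int, rng: np.random.Generator) -> ItemResponses:
    rest = total - item9
    if not 0 <= rest <= 24:
        raise ValueError(f"PHQ-9 total {total} infeasible with item 9 = {item9}")
    items = sample_composition(rest, 8, 3, rng) + (item9,)
    return ItemResponses(Instrument.PHQ9, items)


def _gad_items(total: int, rng: np.random.Generator) -> ItemResponses:
    return ItemResponses(Instrument.GAD7, sample_composition(total, 7, 3, rng))


def _audit_items(rng: np.random.Generator) -> ItemResponses:
    first8 = rng.choice(5, size=8, p=[0.50, 0.25, 0.15, 0.07, 0.03])
    last2 = rng.choice([0, 2, 4], size=2, p=[0.85, 0.10, 0.05])
    return ItemResponses(Instrument.AUDIT, tuple(int(v) for v in first8) + tuple(int(v) for v in last2))


def _draw_bands(
    band: SeverityBand, config: SimulationConfig, rng: np.random.Generator
) -> tuple[SeverityBand, SeverityBand]:
    """(phq_band, gad_band) whose maximum equals the drawn overall band."""
    mix = config.comorbidity_given_band[band.name]
    kind = rng.choice(3, p=mix)  # 0 dep-only, 1 anx-only, 2 both
    if kind == 0:
        return band, SeverityBand.NIL_MINIMAL
    if kind == 1:
        return SeverityBand.NIL_MINIMAL, band
    other = SeverityBand(int(rng.integers(SeverityBand.MILD, band + 1)))
    if rng.random() < 0.5:
        return band, other
    return other, band


def simulate_timeline(
    baseline: TriageResult,
    phq_total: int,
    gad_total: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PatientTimeline:
    """Generate the fortnightly follow-up trajectory for one positive patient."""
    slope_phq = rng.normal(config.phq_trajectory.slope_mean, config.phq_trajectory.slope_sd)
    slope_gad = rng.normal(config.gad_trajectory.slope_mean, config.gad_trajectory.slope_sd)

    # Monotone dropout fortnight (1-based; > 9 means never) and opt-out.
    dropout_after = 10
    if rng.random() < config.p_never_engage:
        dropout_after = 1
    else:
        # Engagers attempt the first fortnight; the hazard acts between
        # subsequent assessments.
        for j in range(2, 10):
            if rng.random() < config.dropout_hazard:
                dropout_after = j
                break
    opted_out_week = None
    for j in range(1, 10):
        if rng.random() < config.optout_hazard:
            opted_out_week = SCHEDULE_WEEKS[j - 1]
            break

    followups = []
    for j, week in enumerate(SCHEDULE_WEEKS, start=1):
        if opted_out_week is not None and week > opted_out_week:
            break
        missed = j >= dropout_after or rng.random() < config.intermittent_miss
        if missed:
            followups.append(FollowUpAssessment(week=week, completed=False))
            continue
        latent_phq = phq_total + slope_phq * j + rng.normal(0, config.phq_trajectory.noise_sd)
        latent_gad = gad_total + slope_gad * j + rng.normal(0, config.gad_trajectory.noise_sd)
        t_phq = int(np.clip(round(latent_phq), 0, PHQ9_CUTOFFS.max_total))
        t_gad = int(np.clip(round(latent_gad), 0, GAD7_CUTOFFS.max_total))
        followups.append(
            FollowUpAssessment(
                week=week,
                completed=True,
                phq9=ItemResponses(Instrument.PHQ9, sample_composition(t_phq, 9, 3, rng)),
                gad7=_gad_items(t_gad, rng),
            )
        )
    return PatientTimeline(
        patient_id=baseline.patient_id,
        baseline=baseline,
        followups=tuple(followups),
        opted_out_week=opted_out_week,
    )


def _draw_prescription(
    band: SeverityBand, config: SimulationConfig, rng: np.random.Generator
) -> frozenset[Treatment]:
    probs = config.gp_prescribe_probs[band.name]
    return frozenset(
        Treatment(cat) for cat, p in probs.items() if rng.random() < p
    )


def _draw_use(
    prescribed: frozenset[Treatment] | None,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> frozenset[Treatment]:
    from .analytics import DIGITAL_TREATMENTS, HIGH_INTENSITY_TREATMENTS

    used: set[Treatment] = set()
    for group, p_uptake, p_bg in (
        (DIGITAL_TREATMENTS, config.uptake_digital, config.background_use_digital),
        (
            HIGH_INTENSITY_TREATMENTS,
            config.uptake_high_intensity,
            config.background_use_high_intensity,
        ),
    ):
        in_group = sorted(group, key=lambda t: t.value)
        prescribed_in_group = sorted(
            (prescribed or frozenset()) & group, key=lambda t: t.value
        )
        p = p_uptake if prescribed_in_group else p_bg
        if rng.random() < p:
            pool = prescribed_in_group or in_group
            used.add(pool[int(rng.integers(len(pool)))])
    return frozenset(used)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from a configuration.

    Deterministic: the cohort is a pure function of the config (including
    its seed).
    """
    rng = np.random.default_rng(config.seed)
    n_completed = 0
    records: list[ScreeningRecord] = []
    results: list[TriageResult] = []
    treatment_records: list[PatientTreatmentRecord] = []
    timelines: list[PatientTimeline] = []

    for i in range(config.n_offered):
        if rng.random() >= config.p_complete:
            continue
        n_completed += 1
        if rng.random() >= config.p_eligible:
            continue
        pid = f"P{i:06d}"
        age = max(18.0, float(rng.normal(config.age_mean, config.age_sd)))
        sex = "F" if rng.random() < config.p_female else "M"

        positive = rng.random() < config.p_positive
        if positive:
            overall = _BANDS_POS[int(rng.choice(3, p=config.severity_mixture))]
            phq_band, gad_band = _draw_bands(overall, config, rng)
            suicidal = rng.random() < config.p_suicidal_given_positive
            item9 = (
                1 + int(rng.choice(3, p=config.suicidality_level_weights))
                if suicidal
                else 0
            )
            # PHQ-9 items 1-8 cap at 24, so the total must lie in
            # [item9, item9 + 24] to be composable with item 9 pinned.
            phq_total = _sample_total(
                phq_band, PHQ9_CUTOFFS, rng, min_total=item9, max_total=item9 + 24
            )
            gad_total = _sample_total(gad_band, GAD7_CUTOFFS, rng)
            unidentified = rng.random() < config.p_unidentified_given_positive
            if unidentified:
                prior, current = False, False
            else:
                current = rng.random() < config.p_current_visit_mh_given_identified
                prior = rng.random() < config.p_prior_contact_given_identified
                if not (prior or current):
                    prior = True
        else:
            phq_band = gad_band = SeverityBand.NIL_MINIMAL
            item9 = 0
            phq_total = _sample_total(phq_band, PHQ9_CUTOFFS, rng)
            gad_total = _sample_total(gad_band, GAD7_CUTOFFS, rng)
            prior = rng.random() < config.p_prior_contact_negative
            current = rng.random() < config.p_current_visit_negative

        record = ScreeningRecord(
            patient_id=pid,
            age=age,
            sex=sex,
            contact_detail_present=True,
            screened_within_6_months=False,
            prior_gp_mh_contact=prior,
            current_visit_mh=current,
            phq9=_phq_items(phq_total, item9, rng),
            gad7=_gad_items(gad_total, rng),
            audit=_audit_items(rng),
        )
        result = triage(record)
        records.append(record)
        results.append(result)

        if result.screen_positive:
            prescribed = (
                _draw_prescription(result.overall_band, config, rng)
                if rng.random() < config.p_rx_data
                else None
            )
            used = (
                _draw_use(prescribed, config, rng)
                if rng.random() < config.p_use_data
                else None
            )
            treatment_records.append(
                PatientTreatmentRecord(
                    patient_id=pid,
                    recommended=result.recommended_treatments,
                    prescribed=prescribed,
                    used=used,
                )
            )
            timelines.append(
                simulate_timeline(result, phq_total, gad_total, config, rng)
            )

    return SyntheticCohort(
        config=config,
        seed=config.seed,
        n_offered=config.n_offered,
        n_completed=n_completed,
        n_eligible=len(records),
        records=tuple(records),
        triage_results=tuple(results),
        treatment_records=tuple(treatment_records),
        timelines=tuple(timelines),
    )


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricRecovery:
    name: str
    truth: float | None
    mean: float
    sd: float
    mc_se: float

    @property
    def within_3se(self) -> bool | None:
        if self.truth is None:
            return None
        if self.mc_se == 0:
            return self.mean == self.truth
        return abs(self.mean - self.truth) <= 3 * self.mc_se


@dataclass(frozen=True)
class RecoveryReport:
    n_reps: int
    metrics: dict[str, MetricRecovery] = field(default_factory=dict)

    @property
    def all_recovered(self) -> bool:
        return all(
            m.within_3se for m in self.metrics.values() if m.within_3se is not None
        )


def parameter_recovery_report(config: SimulationConfig, n_reps: int) -> RecoveryReport:
    """Run the full engine over replicated cohorts and compare recovered
    rates with their config-implied truths.

    Closed-form truths exist for the detection rate (``p_positive``), the
    previously-unidentified fraction (``p_unidentified_given_positive``)
    and the NNS, whose identification risk is the product of the cascade
    probabilities ``p_complete * p_eligible * p_positive *
    p_unidentified``.  Remission and response rates have no closed form
    under the trajectory model and are reported with Monte-Carlo CIs only.
    """
    from .analytics import nns as nns_stat, remission_response_rates

    det, unid, nns_vals, rem, resp = [], [], [], [], []
    for rep in range(n_reps):
        cfg = config.model_copy(update={"seed": (config.seed + 1_000_003 * (rep + 1)) % (2**31)})
        cohort = simulate_cohort(cfg)
        det.append(cohort.n_positive / cohort.n_eligible)
        if cohort.n_positive:
            unid.append(cohort.n_unidentified / cohort.n_positive)
        if cohort.n_unidentified:
            nns_vals.append(nns_stat(cohort.n_unidentified, cohort.n_offered).nns)
        try:
            rates = remission_response_rates(list(cohort.timelines))
            rem.append(rates.remitter_rate.value)
            resp.append(rates.responder_rate.value)
        except Exception:
            pass

    cascade_risk = (
        config.p_complete
        * config.p_eligible
        * config.p_positive
        * config.p_unidentified_given_positive
    )
    truths = {
        "detection_rate": config.p_positive,
        "unidentified_fraction": config.p_unidentified_given_positive,
        "nns": 1.0 / cascade_risk if cascade_risk > 0 else None,
        "remitter_rate": None,
        "responder_rate": None,
    }
    samples = {
        "detection_rate": det,
        "unidentified_fraction": unid,
        "nns": nns_vals,
        "remitter_rate": rem,
        "responder_rate": resp,
    }
    metrics = {}
    for name, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            continue
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        metrics[name] = MetricRecovery(
            name=name,
            truth=truths[name],
            mean=float(arr.mean()),
            sd=sd,
            mc_se=sd / math.sqrt(arr.size) if arr.size else 0.0,
        )
    return RecoveryReport(n_reps=n_reps, metrics=metrics)
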