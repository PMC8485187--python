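"""Cohort-level analytics: detection and severity distributions, number
needed to screen (NNS), recommendation/prescribing/use concordance,
remission/response rates, and effect-size arithmetic.

Every proportion is carried as its numerator/denominator pair; rounding
happens only at presentation (half-up, matching how clinical journals
print rates).  The NNS confidence interval is obtained by computing a
confidence interval for the absolute risk of new identification and
inverting it onto the NNS scale (bounds swap under the reciprocal).  The
default risk-scale interval is Wald; Wilson is available as an
alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from statsmodels.stats.proportion import proportion_confint

from .bands import SeverityBand
from .errors import AnalyticsError, NonCompleterError
from .monitoring import (
    PatientTimeline,
    classify_remitter,
    classify_responder,
    classify_worsened,
    is_completer,
)
from .triage import Treatment, TriageResult

__all__ = [
    "Proportion",
    "CohortSummary",
    "NNSResult",
    "ConcordanceTable",
    "PatientTreatmentRecord",
    "RemissionResponseRates",
    "round_half_up",
    "summarize_cohort",
    "nns",
    "concordance",
    "remission_response_rates",
    "cohen_d",
    "DIGITAL_TREATMENTS",
    "HIGH_INTENSITY_TREATMENTS",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, the convention used when printing rates."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Proportion:
    """A rate that remembers its count pair, so every printed percentage is
    recomputable from the retained numerator and denominator."""

    numerator: int
    denominator: int

    def __post_init__(self):
        if self.denominator < 0 or self.numerator < 0 or self.numerator > self.denominator:
            raise AnalyticsError(
                f"invalid count pair {self.numerator}/{self.denominator}"
            )

    @property
    def value(self) -> float:
        if self.denominator == 0:
            raise AnalyticsError("proportion with zero denominator")
        return self.numerator / self.denominator

    def pct(self, ndigits: int = 2) -> float:
        return round_half_up(100 * self.value, ndigits)

    def __str__(self):
        return f"{self.numerator}/{self.denominator}"


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

_Comorbidity = dict[str, int]  # keys: depression_only, anxiety_only, both


@dataclass(frozen=True)
class CohortSummary:
    n_offered: int
    n_completed: int
    n_eligible: int
    n_positive: int
    band_histogram: dict[SeverityBand, int]
    comorbidity: dict[SeverityBand, _Comorbidity]
    n_suicidal: int
    n_unidentified: int
    completion_rate: Proportion
    eligibility_rate: Proportion
    detection_rate: Proportion
    band_rates: dict[SeverityBand, Proportion]
    suicidal_rate: Proportion
    unidentified_rate: Proportion


def summarize_cohort(
    results: list[TriageResult], n_offered: int, n_completed: int
) -> CohortSummary:
    """Summarise a triaged (eligible) cohort.

    ``results`` are the eligible, triaged patients; ``n_offered`` and
    ``n_completed`` record the top of the screening cascade so the
    completion and eligibility rates keep their true denominators.
    """
    n_eligible = len(results)
    if n_eligible == 0:
        raise AnalyticsError("empty cohort")
    if not n_offered >= n_completed >= n_eligible:
        raise AnalyticsError(
            f"cascade violated: offered {n_offered} >= completed {n_completed} "
            f">= eligible {n_eligible} required"
        )

    positives = [r for r in results if r.screen_positive]
    hist = {band: 0 for band in SeverityBand}
    comorb: dict[SeverityBand, _Comorbidity] = {
        band: {"depression_only": 0, "anxiety_only": 0, "both": 0}
        for band in (SeverityBand.MILD, SeverityBand.MODERATE, SeverityBand.SEVERE)
    }
    for r in results:
        hist[r.overall_band] += 1
    for r in positives:
        dep = r.phq_band >= SeverityBand.MILD
        anx = r.gad_band >= SeverityBand.MILD
        key = "both" if (dep and anx) else ("depression_only" if dep else "anxiety_only")
        comorb[r.overall_band][key] += 1

    n_positive = len(positives)
    n_suicidal = sum(1 for r in positives if r.suicidality >= 1)
    n_unidentified = sum(1 for r in positives if r.previously_unidentified)

    return CohortSummary(
        n_offered=n_offered,
        n_completed=n_completed,
        n_eligible=n_eligible,
        n_positive=n_positive,
        band_histogram=hist,
        comorbidity=comorb,
        n_suicidal=n_suicidal,
        n_unidentified=n_unidentified,
        completion_rate=Proportion(n_completed, n_offered),
        eligibility_rate=Proportion(n_eligible, n_offered),
        detection_rate=Proportion(n_positive, n_eligible),
        band_rates={band: Proportion(hist[band], n_eligible) for band in SeverityBand},
        suicidal_rate=Proportion(n_suicidal, n_positive) if n_positive else Proportion(0, 0),
        unidentified_rate=Proportion(n_unidentified, n_positive)
        if n_positive
        else Proportion(0, 0),
    )


# ---------------------------------------------------------------------------
# Number needed to screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NNSResult:
    """Number needed to screen with its risk-scale inputs and CI.

    Under the no-screening counterfactual nobody is newly identified, so
    the absolute risk difference (ARD) equals the absolute risk of new
    identification under screening and NNS = 1/ARD.
    """

    n_unidentified: int
    n_offered: int
    ar_screening: float
    ar_no_screening: float
    ard: float
    nns: float
    ci_low: float
    ci_high: float
    alpha: float
    ci_method: str

    def formatted(self, ndigits: int = 1) -> str:
        level = round_half_up(100 * (1 - self.alpha))
        return (
            f"{round_half_up(self.nns, ndigits)} ({level:g}% CI "
            f"{round_half_up(self.ci_low, ndigits)}-{round_half_up(self.ci_high, ndigits)})"
        )


def nns(
    n_unidentified: int,
    n_offered: int,
    alpha: float = 0.05,
    ci_method: str = "wald",
) -> NNSResult:
    """Number needed to screen to newly identify one symptomatic patient.

    The CI is computed for the identification risk ``n_unidentified /
    n_offered`` (Wald by default, Wilson optionally) and inverted: the
    upper risk bound becomes the lower NNS bound and vice versa.
    """
    if not 0 < n_unidentified <= n_offered:
        raise AnalyticsError(
            f"need 0 < n_unidentified <= n_offered, got {n_unidentified}/{n_offered}"
        )
    method = {"wald": "normal", "wilson": "wilson"}.get(ci_method)
    if method is None:
        raise AnalyticsError(f"unknown CI method {ci_method!r}")
    ar = n_unidentified / n_offered
    lo, hi = proportion_confint(n_unidentified, n_offered, alpha=alpha, method=method)
    return NNSResult(
        n_unidentified=n_unidentified,
        n_offered=n_offered,
        ar_screening=ar,
        ar_no_screening=0.0,
        ard=ar,
        nns=1.0 / ar,
        ci_low=1.0 / hi,
        ci_high=(1.0 / lo) if lo > 0 else math.inf,
        alpha=alpha,
        ci_method=ci_method,
    )


# ---------------------------------------------------------------------------
# Recommendation / prescribing / use concordance
# ---------------------------------------------------------------------------

# Category normalisation: a "consider X" recommendation counts as a
# recommendation of X when tabulated.
_CANONICAL = {
    Treatment.MEDICATION_CONSIDER: Treatment.MEDICATION,
    Treatment.PSYCHIATRIST_CONSIDER: Treatment.PSYCHIATRIST,
}

CATEGORIES: tuple[Treatment, ...] = (
    Treatment.WEB_SELF_HELP,
    Treatment.GUIDED_WEB_THERAPY,
    Treatment.PSYCHOLOGIST,
    Treatment.MEDICATION,
    Treatment.PSYCHIATRIST,
)

DIGITAL_TREATMENTS = frozenset({Treatment.WEB_SELF_HELP, Treatment.GUIDED_WEB_THERAPY})
HIGH_INTENSITY_TREATMENTS = frozenset(
    {Treatment.PSYCHOLOGIST, Treatment.MEDICATION, Treatment.PSYCHIATRIST}
)


def _canon(treatments: frozenset[Treatment]) -> frozenset[Treatment]:
    return frozenset(_CANONICAL.get(t, t) for t in treatments)


@dataclass(frozen=True)
class PatientTreatmentRecord:
    """Per-patient treatment data: the tool's recommendation, the GP's
    prescription (None when the GP recorded nothing) and the patient's
    reported use (None when no use survey was returned)."""

    patient_id: str
    recommended: frozenset[Treatment]
    prescribed: frozenset[Treatment] | None = None
    used: frozenset[Treatment] | None = None


@dataclass(frozen=True)
class ConcordanceTable:
    """Counts of recommended / prescribed / used treatments per category.

    Categories are not mutually exclusive, so columns do not sum to their
    denominators.  Denominators shift with data availability: recommended
    rates are over all symptomatic patients, prescribed rates over
    patients with prescribing data, use rates over patients with use data,
    and uptake rates over patients with both.
    """

    n_patients: int
    n_with_rx: int
    n_with_use: int
    n_with_both: int
    recommended: dict[Treatment, Proportion]
    prescribed: dict[Treatment, Proportion]
    used: dict[Treatment, Proportion]
    recommended_digital: Proportion
    recommended_high_intensity: Proportion
    prescribed_digital: Proportion
    prescribed_high_intensity: Proportion
    uptake_digital: Proportion
    uptake_high_intensity: Proportion


def _group_count(patients, group: frozenset[Treatment]) -> int:
    return sum(1 for s in patients if s & group)


def concordance(records: list[PatientTreatmentRecord]) -> ConcordanceTable:
    """Tabulate tool recommendations against GP prescriptions and patient use.

    Missing prescribing/use surveys are handled by complete-case
    denominators; no imputation.  Aggregate digital and high-intensity
    groupings (and the recommended aggregates) are computed over the
    prescribing-data subset so recommended and prescribed rates share a
    denominator; uptake is conditional on prescription of the grouping
    among patients with both data types.
    """
    n = len(records)
    rx = [r for r in records if r.prescribed is not None]
    use = [r for r in records if r.used is not None]
    both = [r for r in records if r.prescribed is not None and r.used is not None]

    rec_sets = [_canon(r.recommended) for r in records]
    rx_rec_sets = [_canon(r.recommended) for r in rx]
    rx_sets = [_canon(r.prescribed) for r in rx]
    use_sets = [_canon(r.used) for r in use]

    def per_category(sets, denom):
        return {
            cat: Proportion(sum(1 for s in sets if cat in s), denom)
            for cat in CATEGORIES
        }

    def uptake(group):
        prescribed_group = [
            r for r in both if _canon(r.prescribed) & group
        ]
        used_group = sum(1 for r in prescribed_group if _canon(r.used) & group)
        return Proportion(used_group, len(prescribed_group))

    return ConcordanceTable(
        n_patients=n,
        n_with_rx=len(rx),
        n_with_use=len(use),
        n_with_both=len(both),
        recommended=per_category(rec_sets, n),
        prescribed=per_category(rx_sets, len(rx)),
        used=per_category(use_sets, len(use)),
        recommended_digital=Proportion(
            _group_count(rx_rec_sets, DIGITAL_TREATMENTS), len(rx)
        ),
        recommended_high_intensity=Proportion(
            _group_count(rx_rec_sets, HIGH_INTENSITY_TREATMENTS), len(rx)
        ),
        prescribed_digital=Proportion(_group_count(rx_sets, DIGITAL_TREATMENTS), len(rx)),
        prescribed_high_intensity=Proportion(
            _group_count(rx_sets, HIGH_INTENSITY_TREATMENTS), len(rx)
        ),
        uptake_digital=uptake(DIGITAL_TREATMENTS),
        uptake_high_intensity=uptake(HIGH_INTENSITY_TREATMENTS),
    )


# ---------------------------------------------------------------------------
# Remission / response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RemissionResponseRates:
    n_monitored: int
    n_completers: int
    remitter_rate: Proportion
    responder_rate: Proportion
    worsened_rate: Proportion


def remission_response_rates(
    timelines: list[PatientTimeline], worsened_at_any_point: bool = False
) -> RemissionResponseRates:
    """Completer-analysis remitter / responder / worsened rates.

    Completers are patients with at least one completed follow-up; the
    three classes are not mutually exclusive (a patient can respond on one
    instrument and worsen on the other).
    """
    completers = [t for t in timelines if is_completer(t)]
    if not completers:
        raise AnalyticsError("no patient completed a follow-up assessment")
    n = len(completers)
    try:
        n_rem = sum(classify_remitter(t) for t in completers)
        n_resp = sum(classify_responder(t) for t in completers)
        n_worse = sum(
            classify_worsened(t, at_any_point=worsened_at_any_point) for t in completers
        )
    except NonCompleterError:  # pragma: no cover - filtered above
        raise
    return RemissionResponseRates(
        n_monitored=len(timelines),
        n_completers=n,
        remitter_rate=Proportion(n_rem, n),
        responder_rate=Proportion(n_resp, n),
        worsened_rate=Proportion(n_worse, n),
    )


# ---------------------------------------------------------------------------
# Effect size
# ---------------------------------------------------------------------------


def cohen_d(mean_change: float, baseline_sd: float) -> float:
    """Standardised mean change: |mean change| / baseline SD.

    Used for the longitudinal symptom-change effect sizes, where the mean
    change comes from an externally fitted repeated-measures model and the
    SD is the observed baseline standard deviation.
    """
    if baseline_sd <= 0:
        raise AnalyticsError(f"baseline SD must be positive, got {baseline_sd}")
    return abs(mean_change) / baseline_sd
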