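"""Reference cohort: the published general-practice study counts, encoded
as constructible in-memory fixtures.

The engine was developed around an Australian general-practice screening
cohort (5138 patients offered screening, 3777 completed, 3314 eligible,
1428 screen-positive).  The study's patient-level data are not deposited,
but its printed count tables fully determine the cohort-level statistics,
so this module rebuilds minimal patient-level objects that reproduce every
printed count: band histogram, comorbidity mix, suicidality and
prior-identification tallies, recommendation/prescribing/use margins, and
remission/response outcomes.  Running the analytics over these fixtures
must recover the published rates exactly.

Two of the printed comorbidity breakdowns sum slightly short of their band
totals (mild 346+54+49=449 of 458; moderate 202+28+349=579 of 586; severe
7+13+362=382 of 384); the residual patients are filled in as
depression-only, which leaves every other printed margin intact.
"""

from __future__ import annotations

from .analytics import PatientTreatmentRecord
from .instruments import Instrument, ItemResponses
from .monitoring import FollowUpAssessment, PatientTimeline
from .triage import ScreeningRecord, Treatment, TriageResult, triage

__all__ = [
    "COUNTS",
    "phq9_items_for_total",
    "gad7_items_for_total",
    "reference_screening_records",
    "reference_triage_results",
    "reference_treatment_records",
    "reference_timelines",
]

# Printed study counts.
COUNTS = {
    "n_offered": 5138,
    "n_completed": 3777,
    "n_eligible": 3314,
    "n_positive": 1428,
    "band": {"MILD": 458, "MODERATE": 586, "SEVERE": 384},
    # (depression-only, anxiety-only, both) as printed, per band.
    "comorbidity": {
        "MILD": (346, 54, 49),
        "MODERATE": (202, 28, 349),
        "SEVERE": (7, 13, 362),
    },
    "n_suicidal": 454,
    "n_unidentified": 335,
    "unidentified_by_band": {"MILD": 184, "MODERATE": 116, "SEVERE": 35},
    # GP prescribing subset (Table-shaped margins).
    "n_rx": 334,
    "rx_by_band": {"MILD": 101, "MODERATE": 140, "SEVERE": 93},
    "prescribed": {
        "WEB_SELF_HELP": 60,
        "GUIDED_WEB_THERAPY": 54,
        "PSYCHOLOGIST": 135,
        "MEDICATION": 109,
        "PSYCHIATRIST": 31,
    },
    "prescribed_digital": 103,
    "prescribed_high_intensity": 188,
    "n_use": 606,
    "n_both": 165,
    "uptake_digital": (35, 52),
    "uptake_high_intensity": (96, 102),
    # Completer outcomes.
    "n_completers": 708,
    "n_remitters": 185,
    "n_responders": 392,
    "n_worsened": 185,
    # Effect-size inputs: (modelled 18-week mean change, baseline SD).
    "phq_change_sd": (3.62, 6.20),
    "gad_change_sd": (1.45, 6.62),
}

# Representative totals per band (any total inside the band is equivalent
# for band-level statistics).
_PHQ_TOTAL = {"NIL": 2, "MILD": 7, "MODERATE": 12, "SEVERE": 22}
_GAD_TOTAL = {"NIL": 2, "MILD": 7, "MODERATE": 12, "SEVERE": 16}


def _fill(total: int, k: int, cap: int) -> list[int]:
    items = []
    for _ in range(k):
        take = min(cap, total)
        items.append(take)
        total -= take
    if total:
        raise ValueError(f"total exceeds {k} items capped at {cap}")
    return items


def phq9_items_for_total(total: int, item9: int | None = None) -> ItemResponses:
    """A deterministic PHQ-9 item vector with the given total and item 9.

    When ``item9`` is not given it defaults to the smallest level the total
    permits (0 unless the total exceeds 24, which items 1-8 cannot carry).
    """
    if item9 is None:
        item9 = max(0, total - 24)
    return ItemResponses(Instrument.PHQ9, tuple(_fill(total - item9, 8, 3)) + (item9,))


def gad7_items_for_total(total: int) -> ItemResponses:
    return ItemResponses(Instrument.GAD7, tuple(_fill(total, 7, 3)))


def _record(
    pid: str,
    phq_total: int,
    gad_total: int,
    item9: int = 0,
    prior: bool = True,
    current: bool = False,
) -> ScreeningRecord:
    return ScreeningRecord(
        patient_id=pid,
        age=43.0,
        sex="F",
        contact_detail_present=True,
        screened_within_6_months=False,
        prior_gp_mh_contact=prior,
        current_visit_mh=current,
        phq9=phq9_items_for_total(phq_total, item9),
        gad7=gad7_items_for_total(gad_total),
        audit=ItemResponses(Instrument.AUDIT, (0,) * 10),
    )


def reference_screening_records() -> list[ScreeningRecord]:
    """The 3314 eligible baseline records implied by the printed counts."""
    records: list[ScreeningRecord] = []
    n_suicidal_left = COUNTS["n_suicidal"]
    pid = 0

    for band in ("MILD", "MODERATE", "SEVERE"):
        dep, anx, both = COUNTS["comorbidity"][band]
        residual = COUNTS["band"][band] - (dep + anx + both)
        dep += residual  # see module docstring
        unid_left = COUNTS["unidentified_by_band"][band]
        for kind, n in (("dep", dep), ("anx", anx), ("both", both)):
            for _ in range(n):
                phq = _PHQ_TOTAL[band if kind != "anx" else "NIL"]
                gad = _GAD_TOTAL[band if kind != "dep" else "NIL"]
                item9 = 1 if n_suicidal_left > 0 else 0
                n_suicidal_left -= item9
                unidentified = unid_left > 0
                unid_left -= unidentified
                records.append(
                    _record(
                        f"R{pid:05d}",
                        phq,
                        gad,
                        item9=item9,
                        prior=not unidentified,
                        current=False,
                    )
                )
                pid += 1

    n_negative = COUNTS["n_eligible"] - COUNTS["n_positive"]
    for _ in range(n_negative):
        records.append(_record(f"R{pid:05d}", _PHQ_TOTAL["NIL"], _GAD_TOTAL["NIL"]))
        pid += 1
    return records


def reference_triage_results() -> list[TriageResult]:
    return [triage(r) for r in reference_screening_records()]


def _rx_assignment() -> list[frozenset[Treatment]]:
    """Prescribed sets for the 334-patient prescribing subset.

    Index-range design satisfying every printed margin simultaneously:
    per-category counts, the digital union (103) and the high-intensity
    union (188).
    """
    T = Treatment
    sets: list[set[Treatment]] = [set() for _ in range(COUNTS["n_rx"])]
    for i in range(0, 60):
        sets[i].add(T.WEB_SELF_HELP)
    for i in range(49, 103):
        sets[i].add(T.GUIDED_WEB_THERAPY)
    for i in range(110, 245):
        sets[i].add(T.PSYCHOLOGIST)
    for i in range(189, 298):
        sets[i].add(T.MEDICATION)
    for i in range(110, 141):
        sets[i].add(T.PSYCHIATRIST)
    return [frozenset(s) for s in sets]


def _recommended_for_band(band: str) -> frozenset[Treatment]:
    T = Treatment
    if band == "MILD":
        return frozenset({T.WEB_SELF_HELP})
    if band == "MODERATE":
        return frozenset({T.GUIDED_WEB_THERAPY, T.PSYCHOLOGIST, T.MEDICATION_CONSIDER})
    return frozenset({T.PSYCHOLOGIST, T.MEDICATION, T.PSYCHIATRIST_CONSIDER})


def reference_treatment_records() -> list[PatientTreatmentRecord]:
    """The 1428 symptomatic patients' treatment data.

    The first 334 carry GP prescribing data (bands 101 mild / 140 moderate
    / 93 severe); 165 of the 334 plus 441 others carry patient-use data,
    arranged so the digital and high-intensity uptake fractions match the
    printed 35/52 and 96/102.
    """
    T = Treatment
    digital = {T.WEB_SELF_HELP, T.GUIDED_WEB_THERAPY}
    high = {T.PSYCHOLOGIST, T.MEDICATION, T.PSYCHIATRIST}

    rx_sets = _rx_assignment()
    rx_bands = ["MILD"] * 101 + ["MODERATE"] * 140 + ["SEVERE"] * 93
    # Use-data membership within the prescribing subset: 52 digital-
    # prescribed (indices 0-51), 102 high-prescribed (110-211), 11 with an
    # empty prescription (298-308) -> 165 patients with both data types.
    both_idx = set(range(0, 52)) | set(range(110, 212)) | set(range(298, 309))
    records: list[PatientTreatmentRecord] = []
    for i in range(COUNTS["n_rx"]):
        used = None
        if i in both_idx:
            used_set: set[Treatment] = set()
            if i < 35:  # 35 of the 52 digital-prescribed used a digital one
                used_set.add(sorted(rx_sets[i] & digital, key=lambda t: t.value)[0])
            if 110 <= i < 206:  # 96 of the 102 high-prescribed used one
                used_set.add(sorted(rx_sets[i] & high, key=lambda t: t.value)[0])
            used = frozenset(used_set)
        records.append(
            PatientTreatmentRecord(
                patient_id=f"T{i:05d}",
                recommended=_recommended_for_band(rx_bands[i]),
                prescribed=rx_sets[i],
                used=used,
            )
        )

    # Remaining symptomatic patients: band mix completes the printed
    # totals (458 mild, 586 moderate, 384 severe across all 1428).
    rest_bands = ["MILD"] * 357 + ["MODERATE"] * 446 + ["SEVERE"] * 291
    n_use_only = COUNTS["n_use"] - len(
        [i for i in both_idx]
    )  # 606 - 165 = 441 use-data-only patients
    for j, band in enumerate(rest_bands):
        i = COUNTS["n_rx"] + j
        records.append(
            PatientTreatmentRecord(
                patient_id=f"T{i:05d}",
                recommended=_recommended_for_band(band),
                prescribed=None,
                used=frozenset() if j < n_use_only else None,
            )
        )
    return records


def _timeline(
    pid: str,
    phq0: int,
    gad0: int,
    phq_last: int | None,
    gad_last: int | None,
) -> PatientTimeline:
    baseline = triage(_record(pid, phq0, gad0))
    followups: tuple[FollowUpAssessment, ...]
    if phq_last is None:
        followups = ()
    else:
        followups = (
            FollowUpAssessment(
                week=2,
                completed=True,
                phq9=phq9_items_for_total(phq_last),
                gad7=gad7_items_for_total(gad_last),
            ),
        )
    return PatientTimeline(patient_id=pid, baseline=baseline, followups=followups)


def reference_timelines() -> list[PatientTimeline]:
    """1428 monitored patients: 708 completers whose last-assessment bands
    yield the printed 185 remitters, 392 responders and 185 worsened, plus
    720 patients with no completed follow-up."""
    timelines = []
    i = 0

    def add(n, phq0, gad0, phq_last, gad_last):
        nonlocal i
        for _ in range(n):
            timelines.append(_timeline(f"M{i:05d}", phq0, gad0, phq_last, gad_last))
            i += 1

    add(185, 7, 2, 2, 2)  # remitters (also responders: mild -> nil-minimal)
    add(207, 12, 7, 7, 7)  # responders only (moderate -> mild; anxiety static)
    add(185, 7, 2, 12, 2)  # worsened (mild -> moderate)
    add(131, 7, 7, 7, 7)  # band-stable completers
    add(720, 7, 2, None, None)  # never completed a follow-up
    return timelines
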