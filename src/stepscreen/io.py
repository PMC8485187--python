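"""File formats: cohort CSV, timeline JSONL, summary JSON/text/CSV.

Conventions: CSV is comma-separated UTF-8 with a required header
(RFC-4180 quoting via the csv module / pandas); timelines are JSONL, one
patient per line, so cohorts stream.  Row-level validation failures are
collected with their line numbers and column names rather than aborting
or being silently dropped.  Every summary file embeds the package version
and a hash of the engine configuration for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable

import pandas as pd

from . import __version__
from .analytics import (
    CohortSummary,
    ConcordanceTable,
    NNSResult,
    PatientTreatmentRecord,
    RemissionResponseRates,
)
from .bands import SeverityBand
from .config import EngineConfig
from .errors import StepscreenError
from .instruments import Instrument, ItemResponses
from .monitoring import FollowUpAssessment, PatientTimeline
from .triage import ScreeningRecord, Treatment, TriageResult, triage

__all__ = [
    "RowError",
    "read_cohort_csv",
    "write_triage_jsonl",
    "write_timelines_jsonl",
    "read_timelines_jsonl",
    "timelines_to_long_csv",
    "write_treatment_csv",
    "read_treatment_csv",
    "write_summary",
]

_PHQ_COLS = [f"phq9_{i}" for i in range(1, 10)]
_GAD_COLS = [f"gad7_{i}" for i in range(1, 8)]
_AUDIT_COLS = [f"audit_{i}" for i in range(1, 11)]
_BOOL_COLS = [
    "contact_detail_present",
    "screened_within_6_months",
    "prior_gp_mh_contact",
    "current_visit_mh",
]
REQUIRED_COLUMNS = ["patient_id", "age", "sex", *_BOOL_COLS, *_PHQ_COLS, *_GAD_COLS, *_AUDIT_COLS]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


@dataclass(frozen=True)
class RowError:
    """One rejected input row: line number (1-based incl. header), column, reason."""

    line: int
    column: str | None
    message: str


def _parse_bool(raw: Any) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def read_cohort_csv(path: str | Path) -> tuple[list[ScreeningRecord], list[RowError]]:
    """Read baseline screening records, collecting per-row errors.

    Returns (valid records, row errors).  Only an unreadable file or a
    missing required column is fatal.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StepscreenError(f"cohort CSV missing required columns: {missing}")

    records: list[ScreeningRecord] = []
    errors: list[RowError] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            items = {}
            for cols, instrument in (
                (_PHQ_COLS, Instrument.PHQ9),
                (_GAD_COLS, Instrument.GAD7),
                (_AUDIT_COLS, Instrument.AUDIT),
            ):
                values = []
                for c in cols:
                    try:
                        values.append(int(row[c]))
                    except ValueError:
                        raise _ColumnError(c, f"non-integer item {row[c]!r}") from None
                try:
                    items[instrument] = ItemResponses(instrument, tuple(values))
                except StepscreenError as exc:
                    col = cols[exc.index] if getattr(exc, "index", None) is not None else None
                    raise _ColumnError(col, str(exc)) from None
            bools = {}
            for c in _BOOL_COLS:
                try:
                    bools[c] = _parse_bool(row[c])
                except ValueError as exc:
                    raise _ColumnError(c, str(exc)) from None
            try:
                age = float(row["age"])
            except ValueError:
                raise _ColumnError("age", f"non-numeric age {row['age']!r}") from None
            records.append(
                ScreeningRecord(
                    patient_id=str(row["patient_id"]),
                    age=age,
                    sex=str(row["sex"]),
                    phq9=items[Instrument.PHQ9],
                    gad7=items[Instrument.GAD7],
                    audit=items[Instrument.AUDIT],
                    **bools,
                )
            )
        except _ColumnError as exc:
            errors.append(RowError(line, exc.column, exc.message))
        except (StepscreenError, ValueError) as exc:
            errors.append(RowError(line, None, str(exc)))
    return records, errors


class _ColumnError(Exception):
    def __init__(self, column: str | None, message: str):
        super().__init__(message)
        self.column = column
        self.message = message


# ---------------------------------------------------------------------------
# Triage / timeline serialisation
# ---------------------------------------------------------------------------


def _provenance(config: EngineConfig | None) -> dict:
    cfg = config or EngineConfig()
    return {"engine_version": __version__, "config_hash": cfg.config_hash()}


def triage_result_to_dict(result: TriageResult) -> dict:
    return {
        "patient_id": result.patient_id,
        "phq9_total": result.phq_score.total,
        "gad7_total": result.gad_score.total,
        "audit_total": result.audit_score.total,
        "phq_band": result.phq_band.name,
        "gad_band": result.gad_band.name,
        "overall_band": result.overall_band.name,
        "screen_positive": result.screen_positive,
        "suicidality": result.suicidality.name,
        "supports_enabled": result.supports.any_enabled,
        "step": result.step.value,
        "recommended_treatments": sorted(t.value for t in result.recommended_treatments),
        "previously_unidentified": result.previously_unidentified,
    }


def write_triage_jsonl(
    results: Iterable[TriageResult], path: str | Path, config: EngineConfig | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"_provenance": _provenance(config)}) + "\n")
        for r in results:
            fh.write(json.dumps(triage_result_to_dict(r)) + "\n")


def _record_to_dict(record: ScreeningRecord) -> dict:
    return {
        "patient_id": record.patient_id,
        "age": record.age,
        "sex": record.sex,
        "contact_detail_present": record.contact_detail_present,
        "screened_within_6_months": record.screened_within_6_months,
        "prior_gp_mh_contact": record.prior_gp_mh_contact,
        "current_visit_mh": record.current_visit_mh,
        "phq9": list(record.phq9.items),
        "gad7": list(record.gad7.items),
        "audit": list(record.audit.items),
    }


def _record_from_dict(d: dict) -> ScreeningRecord:
    return ScreeningRecord(
        patient_id=d["patient_id"],
        age=d["age"],
        sex=d["sex"],
        contact_detail_present=d["contact_detail_present"],
        screened_within_6_months=d["screened_within_6_months"],
        prior_gp_mh_contact=d["prior_gp_mh_contact"],
        current_visit_mh=d["current_visit_mh"],
        phq9=ItemResponses(Instrument.PHQ9, tuple(d["phq9"])),
        gad7=ItemResponses(Instrument.GAD7, tuple(d["gad7"])),
        audit=ItemResponses(Instrument.AUDIT, tuple(d["audit"])),
    )


def write_timelines_jsonl(
    timelines: Iterable[PatientTimeline],
    records: Iterable[ScreeningRecord],
    path: str | Path,
    config: EngineConfig | None = None,
) -> None:
    """One patient per line: the baseline record plus the fortnightly rows."""
    by_id = {r.patient_id: r for r in records}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"_provenance": _provenance(config)}) + "\n")
        for t in timelines:
            payload = {
                "baseline": _record_to_dict(by_id[t.patient_id]),
                "opted_out_week": t.opted_out_week,
                "followups": [
                    {
                        "week": f.week,
                        "completed": f.completed,
                        "phq9": list(f.phq9.items) if f.completed else None,
                        "gad7": list(f.gad7.items) if f.completed else None,
                    }
                    for f in t.followups
                ],
            }
            fh.write(json.dumps(payload) + "\n")


def read_timelines_jsonl(
    path: str | Path, severity_policy: str = "max"
) -> list[PatientTimeline]:
    timelines = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            if "_provenance" in d:
                continue
            record = _record_from_dict(d["baseline"])
            baseline = triage(record, severity_policy)
            followups = tuple(
                FollowUpAssessment(
                    week=f["week"],
                    completed=f["completed"],
                    phq9=ItemResponses(Instrument.PHQ9, tuple(f["phq9"]))
                    if f["completed"]
                    else None,
                    gad7=ItemResponses(Instrument.GAD7, tuple(f["gad7"]))
                    if f["completed"]
                    else None,
                )
                for f in d["followups"]
            )
            timelines.append(
                PatientTimeline(
                    patient_id=record.patient_id,
                    baseline=baseline,
                    followups=followups,
                    opted_out_week=d.get("opted_out_week"),
                )
            )
    return timelines


def timelines_to_long_csv(timelines: Iterable[PatientTimeline], path: str | Path) -> None:
    """Long-format export: one row per patient-week, bands included."""
    rows = []
    for t in timelines:
        for f in t.followups:
            rows.append(
                {
                    "patient_id": t.patient_id,
                    "week": f.week,
                    "completed": f.completed,
                    "phq9_total": f.phq9.total if f.completed else None,
                    "gad7_total": f.gad7.total if f.completed else None,
                    "phq_band": f.phq_band.name if f.completed else None,
                    "gad_band": f.gad_band.name if f.completed else None,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Treatment records (recommendation / prescription / use)
# ---------------------------------------------------------------------------

_MISSING = ""  # survey not returned
_EMPTY = "-"  # survey returned, nothing ticked


def _join(treatments: frozenset[Treatment] | None) -> str:
    if treatments is None:
        return _MISSING
    if not treatments:
        return _EMPTY
    return ";".join(sorted(t.value for t in treatments))


def _split(raw: str) -> frozenset[Treatment] | None:
    s = str(raw).strip()
    if s == _MISSING:
        return None
    if s == _EMPTY:
        return frozenset()
    return frozenset(Treatment(t) for t in s.split(";"))


def write_treatment_csv(records: Iterable[PatientTreatmentRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "recommended": _join(r.recommended),
            "prescribed": _join(r.prescribed),
            "used": _join(r.used),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_treatment_csv(path: str | Path) -> list[PatientTreatmentRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    return [
        PatientTreatmentRecord(
            patient_id=row["patient_id"],
            recommended=_split(row["recommended"]) or frozenset(),
            prescribed=_split(row["prescribed"]),
            used=_split(row["used"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _prop(p, ndigits: int = 2) -> dict:
    pct = p.pct(ndigits) if p.denominator else None
    return {"n": p.numerator, "d": p.denominator, "pct": pct}


def summary_to_dict(s: CohortSummary, config: EngineConfig | None = None) -> dict:
    cfg = config or EngineConfig()
    dp = cfg.cohort_pct_decimals
    return {
        "_provenance": _provenance(cfg),
        "n_offered": s.n_offered,
        "n_completed": s.n_completed,
        "n_eligible": s.n_eligible,
        "n_positive": s.n_positive,
        "completion_rate": _prop(s.completion_rate, dp),
        "eligibility_rate": _prop(s.eligibility_rate, dp),
        "detection_rate": _prop(s.detection_rate, dp),
        "band_rates": {b.name: _prop(s.band_rates[b], dp) for b in SeverityBand},
        "comorbidity": {b.name: dict(v) for b, v in s.comorbidity.items()},
        "suicidal_rate": _prop(s.suicidal_rate, dp),
        "unidentified_rate": _prop(s.unidentified_rate, dp),
    }


def nns_to_dict(r: NNSResult, config: EngineConfig | None = None) -> dict:
    return {
        "_provenance": _provenance(config),
        "n_unidentified": r.n_unidentified,
        "n_offered": r.n_offered,
        "ar_screening": r.ar_screening,
        "ar_no_screening": r.ar_no_screening,
        "ard": r.ard,
        "nns": r.nns,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "alpha": r.alpha,
        "ci_method": r.ci_method,
        "formatted": r.formatted(),
    }


def concordance_to_dict(t: ConcordanceTable, config: EngineConfig | None = None) -> dict:
    cfg = config or EngineConfig()
    dp = cfg.table_pct_decimals
    return {
        "_provenance": _provenance(cfg),
        "n_patients": t.n_patients,
        "n_with_rx": t.n_with_rx,
        "n_with_use": t.n_with_use,
        "n_with_both": t.n_with_both,
        "recommended": {k.value: _prop(v, dp) for k, v in t.recommended.items()},
        "prescribed": {k.value: _prop(v, dp) for k, v in t.prescribed.items()},
        "used": {k.value: _prop(v, dp) for k, v in t.used.items()},
        "recommended_digital": _prop(t.recommended_digital, dp),
        "recommended_high_intensity": _prop(t.recommended_high_intensity, dp),
        "prescribed_digital": _prop(t.prescribed_digital, dp),
        "prescribed_high_intensity": _prop(t.prescribed_high_intensity, dp),
        "uptake_digital": _prop(t.uptake_digital, dp)
        if t.uptake_digital.denominator
        else {"n": 0, "d": 0, "pct": None},
        "uptake_high_intensity": _prop(t.uptake_high_intensity, dp)
        if t.uptake_high_intensity.denominator
        else {"n": 0, "d": 0, "pct": None},
    }


def rates_to_dict(r: RemissionResponseRates, config: EngineConfig | None = None) -> dict:
    return {
        "_provenance": _provenance(config),
        "n_monitored": r.n_monitored,
        "n_completers": r.n_completers,
        "remitter_rate": _prop(r.remitter_rate, 1),
        "responder_rate": _prop(r.responder_rate, 1),
        "worsened_rate": _prop(r.worsened_rate, 1),
    }


_SERIALIZERS = {
    CohortSummary: summary_to_dict,
    NNSResult: nns_to_dict,
    ConcordanceTable: concordance_to_dict,
    RemissionResponseRates: rates_to_dict,
}


def write_summary(
    obj, path: str | Path, fmt: str = "json", config: EngineConfig | None = None
) -> None:
    """Write a computed summary as machine JSON or a human-readable text table."""
    serializer = _SERIALIZERS.get(type(obj))
    if serializer is None:
        raise StepscreenError(f"cannot serialise object of type {type(obj).__name__}")
    data = serializer(obj, config)
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    elif fmt == "text":
        path.write_text(_render_text(data), encoding="utf-8")
    elif fmt == "csv" and isinstance(obj, ConcordanceTable):
        _concordance_csv(obj, path)
    else:
        raise StepscreenError(f"unsupported format {fmt!r} for {type(obj).__name__}")


def _render_text(data: dict, indent: int = 0) -> str:
    lines = []
    for key, value in data.items():
        if key == "_provenance":
            lines.append(f"# stepscreen {value['engine_version']} config {value['config_hash']}")
        elif isinstance(value, dict) and {"n", "d", "pct"} <= set(value):
            pct = "NA" if value["pct"] is None else f"{value['pct']}%"
            lines.append(f"{' ' * indent}{key}: {value['n']}/{value['d']} ({pct})")
        elif isinstance(value, dict):
            lines.append(f"{' ' * indent}{key}:")
            lines.append(_render_text(value, indent + 2).rstrip("\n"))
        else:
            lines.append(f"{' ' * indent}{key}: {value}")
    return "\n".join(lines) + "\n"


def _concordance_csv(t: ConcordanceTable, path: Path) -> None:
    rows = []
    for cat in t.recommended:
        rows.append(
            {
                "treatment": cat.value,
                "n_recommended": t.recommended[cat].numerator,
                "pct_recommended": t.recommended[cat].pct(1)
                if t.recommended[cat].denominator
                else None,
                "n_prescribed": t.prescribed[cat].numerator,
                "pct_prescribed": t.prescribed[cat].pct(1)
                if t.prescribed[cat].denominator
                else None,
                "n_used": t.used[cat].numerator,
                "pct_used": t.used[cat].pct(1) if t.used[cat].denominator else None,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
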