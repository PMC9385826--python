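"""Cohort schema, CSV IO, validation, and the observed/estimated ratio sample.

One row per patient: demographics and cancer details as entered by the
oncologist, the estimated survival time (EST, months), the observed
survival time (OST, months, from the scenario consultation to death or
last follow-up), a vital-status indicator, Likert questionnaire
responses in wide ``likert_<qid>`` columns and instrument item responses
in wide ``<instrument>_item<k>`` columns.

Durations are decimal months throughout (1 month = 30.44 days for any
day-level conversion).  Missing values are empty cells; missing-data
handling is per-analysis exclusion, with exclusions counted, never
silent.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "RatioSample",
    "RowRejection",
    "CohortReadResult",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "build_ratio_sample",
    "LIKERT_LEVELS",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"
DAYS_PER_MONTH = 30.44

LIKERT_LEVELS = (
    "strongly_agree", "agree", "unsure", "disagree", "strongly_disagree",
)
SEX_LEVELS = ("male", "female")
EDUCATION_LEVELS = ("year10_or_less", "highschool_or_above", "unknown")
TIME_FROM_DIAGNOSIS_LEVELS = ("le_8_weeks", "gt_8_weeks")
CONSULTATION_LEVELS = ("initial", "second", "third_or_later")
EVENT_LEVELS = ("died", "alive_censored")

CORE_COLUMNS = [
    "patient_id", "age_years", "sex", "cancer_type", "ecog", "education",
    "time_from_diagnosis", "consultation_number", "est_months",
    "ost_months", "event",
]

#: instruments shipped by default, with their item counts (column layout)
INSTRUMENT_ITEMS = {"stai6": 6, "hhi": 12, "lotr": 10}


@dataclass
class PatientRecord:
    """One patient's row in the cohort table."""

    patient_id: str
    age_years: int
    sex: str
    cancer_type: str
    ecog: int
    education: str
    time_from_diagnosis: str
    consultation_number: str
    est_months: float
    ost_months: float | None = None
    event: str | None = None  # "died" / "alive_censored"; None iff ost missing
    likert_responses: dict[str, str] = field(default_factory=dict)
    instrument_items: dict[str, list[int | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.est_months) and self.est_months > 0):
            raise ValueError(
                f"{self.patient_id}: non-positive EST ({self.est_months})")
        if (self.ost_months is None) != (self.event is None):
            raise ValueError(
                f"{self.patient_id}: ost_months and event must be missing "
                "together")
        if self.ost_months is not None and not (
                math.isfinite(self.ost_months) and self.ost_months > 0):
            raise ValueError(
                f"{self.patient_id}: non-positive OST ({self.ost_months})")


@dataclass
class RatioSample:
    """Censoring-aware sample of observed/estimated survival-time ratios.

    ``events[i]`` is 1 when the death was observed and 0 when the patient
    was alive at last follow-up (the ratio then censors at last-known-alive
    time over EST).  Records without survival data are excluded and
    counted, never silently dropped.
    """

    ratios: np.ndarray
    events: np.ndarray
    excluded_count: int = 0

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.ratios.shape != self.events.shape:
            raise ValueError("ratios and events must be parallel")
        if np.any(self.ratios <= 0) or not np.all(np.isfinite(self.ratios)):
            raise ValueError("ratios must be positive and finite")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("events must be 0 (censored) or 1 (death)")

    def __len__(self) -> int:
        return len(self.ratios)


@dataclass(frozen=True)
class RowRejection:
    row: int  # 1-based data row number (header excluded)
    column: str
    reason: str


@dataclass
class CohortReadResult:
    records: list[PatientRecord]
    rejections: list[RowRejection]

    def write_rejection_report(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["row", "column", "reason"])
            for r in self.rejections:
                w.writerow([r.row, r.column, r.reason])


def _columns_for(records: list[PatientRecord]) -> list[str]:
    likert_ids = sorted({q for r in records for q in r.likert_responses})
    inst_cols = []
    seen_inst = {i for r in records for i in r.instrument_items}
    for inst, n in INSTRUMENT_ITEMS.items():
        if inst in seen_inst:
            inst_cols += [f"{inst}_item{k}" for k in range(1, n + 1)]
    return CORE_COLUMNS + [f"likert_{q}" for q in likert_ids] + inst_cols


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(records: list[PatientRecord], path_or_file) -> None:
    """Write the cohort as CSV with the fixed column order."""
    if hasattr(path_or_file, "write"):
        _write_cohort(records, path_or_file)
    else:
        with open(path_or_file, "w", newline="") as fh:
            _write_cohort(records, fh)


def _write_cohort(records: list[PatientRecord], fh) -> None:
    cols = _columns_for(records)
    w = csv.writer(fh, lineterminator="\n")
    w.writerow(cols)
    for r in records:
        row = {c: "" for c in cols}
        for c in CORE_COLUMNS:
            row[c] = _fmt(getattr(r, c))
        for q, resp in r.likert_responses.items():
            row[f"likert_{q}"] = "" if resp is None else resp
        for inst, items in r.instrument_items.items():
            for k, v in enumerate(items, start=1):
                row[f"{inst}_item{k}"] = "" if v is None else str(v)
        w.writerow([row[c] for c in cols])


def _parse_row(idx: int, row: pd.Series, likert_cols, inst_cols,
               rejections: list[RowRejection]) -> PatientRecord | None:
    def bad(column: str, reason: str) -> None:
        rejections.append(RowRejection(idx, column, reason))

    errors_before = len(rejections)

    def get(col: str) -> str:
        return str(row[col]).strip()

    def parse_cat(col: str, levels) -> str | None:
        v = get(col)
        if v not in levels:
            bad(col, f"invalid level {v!r}, expected one of {list(levels)}")
            return None
        return v

    def parse_num(col: str, kind, required: bool, positive=True):
        v = get(col)
        if v == "":
            if required:
                bad(col, "missing required value")
            return None
        try:
            x = kind(v)
        except ValueError:
            bad(col, f"unparseable {kind.__name__} {v!r}")
            return None
        if positive and not (math.isfinite(x) and x > 0):
            bad(col, f"non-positive {col.replace('_months', '').upper()}"
                if col.endswith("_months") else f"non-positive value {x}")
            return None
        return x

    pid = get("patient_id")
    if not pid:
        bad("patient_id", "empty patient id")
    age = parse_num("age_years", int, required=True)
    sex = parse_cat("sex", SEX_LEVELS)
    cancer = get("cancer_type")
    ecog_raw = get("ecog")
    ecog = None
    if ecog_raw not in {"0", "1", "2", "3"}:
        bad("ecog", f"invalid ECOG {ecog_raw!r}")
    else:
        ecog = int(ecog_raw)
    edu = parse_cat("education", EDUCATION_LEVELS)
    tfd = parse_cat("time_from_diagnosis", TIME_FROM_DIAGNOSIS_LEVELS)
    cons = parse_cat("consultation_number", CONSULTATION_LEVELS)
    est = parse_num("est_months", float, required=True)
    ost = parse_num("ost_months", float, required=False)
    ev_raw = get("event")
    event = None
    if ev_raw == "":
        if ost is not None:
            bad("event", "event missing but ost_months present")
    elif ev_raw not in EVENT_LEVELS:
        bad("event", f"invalid event {ev_raw!r}")
    elif ost is None:
        bad("ost_months", "ost_months missing but event present")
    else:
        event = ev_raw
    if event is None:
        ost = None

    likert: dict[str, str] = {}
    for col in likert_cols:
        v = get(col)
        qid = col.removeprefix("likert_")
        if v == "":
            likert[qid] = None
        elif v not in LIKERT_LEVELS:
            bad(col, f"invalid Likert level {v!r}")
        else:
            likert[qid] = v

    instruments: dict[str, list[int | None]] = {}
    for inst, cols in inst_cols.items():
        items: list[int | None] = []
        for col in cols:
            v = get(col)
            if v == "":
                items.append(None)
            else:
                try:
                    items.append(int(v))
                except ValueError:
                    bad(col, f"unparseable item response {v!r}")
                    items.append(None)
        instruments[inst] = items

    if len(rejections) > errors_before:
        return None
    return PatientRecord(
        patient_id=pid, age_years=age, sex=sex, cancer_type=cancer,
        ecog=ecog, education=edu, time_from_diagnosis=tfd,
        consultation_number=cons, est_months=est, ost_months=ost,
        event=event, likert_responses=likert, instrument_items=instruments,
    )


def read_cohort(path, schema_version: str = SCHEMA_VERSION) -> CohortReadResult:
    """Read and validate a cohort CSV.

    Missing mandatory columns are a hard failure; malformed rows are
    collected into the rejection report with row numbers and reasons.
    Lines starting with ``#`` (simulation provenance headers) are ignored.
    """
    if schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {schema_version!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing mandatory columns: {missing}")
    likert_cols = [c for c in df.columns if c.startswith("likert_")]
    inst_cols = {
        inst: cols for inst in INSTRUMENT_ITEMS
        if (cols := [c for c in df.columns if c.startswith(f"{inst}_item")])
    }
    rejections: list[RowRejection] = []
    records: list[PatientRecord] = []
    seen_ids: set[str] = set()
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        rec = _parse_row(i, row, likert_cols, inst_cols, rejections)
        if rec is None:
            continue
        if rec.patient_id in seen_ids:
            rejections.append(
                RowRejection(i, "patient_id",
                             f"duplicate patient id {rec.patient_id!r}"))
            continue
        seen_ids.add(rec.patient_id)
        records.append(rec)
    return CohortReadResult(records=records, rejections=rejections)


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Core (non-questionnaire) fields as a DataFrame, one row per patient."""
    return pd.DataFrame(
        [{c: getattr(r, c) for c in CORE_COLUMNS} for r in records]
    )


def build_ratio_sample(records: list[PatientRecord]) -> RatioSample:
    """Per-patient OST/EST ratios with censoring indicators.

    Records with missing survival data are excluded and counted:
    ``kept + excluded_count == len(records)``.
    """
    ratios, events = [], []
    excluded = 0
    for r in records:
        if r.ost_months is None or r.event is None:
            excluded += 1
            continue
        ratios.append(r.ost_months / r.est_months)
        events.append(1 if r.event == "died" else 0)
    return RatioSample(np.array(ratios), np.array(events),
                       excluded_count=excluded)
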