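"""Delimited-text input/output for diary streams, events and study tables.

All files are UTF-8 delimited text with a header row (comma by default,
tab accepted).  Flags are encoded 0/1.  Column orders are stable and
documented in the README so downstream tooling can rely on them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError
from .records import (
    ALL_SYMPTOMS,
    BACK_ENTRY_WINDOW_DAYS,
    DEFAULT_AVAILABLE_DAYS,
    CensorReason,
    DiaryRecord,
    ExacerbationEvent,
    SymptomSet,
)

FLAG_COLUMNS = list(ALL_SYMPTOMS) + [
    "increased_inhaled_medication",
    "started_antibiotics",
    "started_corticosteroids",
    "contact_scheduled_visit",
    "contact_unscheduled_visit",
    "contact_emergency",
    "contact_hospitalization",
]

DIARY_COLUMNS = ["patient_id", "study_day", "entry_day"] + FLAG_COLUMNS

EVENT_COLUMNS = [
    "patient_id",
    "onset_day",
    "end_day",
    "duration_days",
    "recovery_undetermined",
    "censor_reason",
    "observed_end",
    "onset_symptom_count",
    "severity_bin",
] + list(ALL_SYMPTOMS)


@dataclass(frozen=True)
class IngestResult:
    """Outcome of diary ingestion.

    ``n_input_rows == len(records) + n_dropped_back_entry + n_dropped_duplicate``
    always holds, so every input row is accounted for.
    """

    records: list[DiaryRecord]
    n_input_rows: int
    n_dropped_back_entry: int
    n_dropped_duplicate: int

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_back_entry + self.n_dropped_duplicate


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _parse_flag(value: str, row: int, column: str) -> bool:
    v = value.strip()
    if v == "0":
        return False
    if v == "1":
        return True
    raise SchemaError(f"flag value must be 0 or 1, got {value!r}", row=row, column=column)


def _parse_int(value: str, row: int, column: str) -> int:
    try:
        return int(value.strip())
    except ValueError:
        raise SchemaError(f"expected an integer, got {value!r}", row=row, column=column)


def read_diary(
    path: str | Path,
    delimiter: str | None = None,
    n_days: int = DEFAULT_AVAILABLE_DAYS,
) -> IngestResult:
    """Read a diary file into validated, deduplicated records.

    Rows whose ``entry_day`` falls outside the 3-day back-entry window
    are dropped and counted; duplicate (patient, day) rows are resolved
    by keeping the row with the earliest ``entry_day`` (closest to real
    time).  The returned records are sorted by (patient_id, study_day).
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise SchemaError("diary file is empty (no header row)")
        missing = [c for c in DIARY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"diary file lacks required columns: {missing}")
        best: dict[tuple[str, int], DiaryRecord] = {}
        n_rows = 0
        n_back = 0
        n_dup = 0
        for i, row in enumerate(reader, start=2):  # 1-based, header is row 1
            n_rows += 1
            pid = row["patient_id"].strip()
            if not pid:
                raise SchemaError("patient_id is empty", row=i, column="patient_id")
            day = _parse_int(row["study_day"], i, "study_day")
            if not (1 <= day <= n_days):
                raise SchemaError(
                    f"study_day {day} outside the 1..{n_days} window",
                    row=i,
                    column="study_day",
                )
            entry = row.get("entry_day", "").strip()
            entry_day = day if entry == "" else _parse_int(entry, i, "entry_day")
            if not (day <= entry_day <= day + BACK_ENTRY_WINDOW_DAYS):
                n_back += 1
                continue
            flags = {c: _parse_flag(row[c], i, c) for c in FLAG_COLUMNS}
            rec = DiaryRecord(
                patient_id=pid,
                study_day=day,
                symptoms=SymptomSet(**{s: flags[s] for s in ALL_SYMPTOMS}),
                entry_day=entry_day,
                **{k: flags[k] for k in FLAG_COLUMNS if k not in ALL_SYMPTOMS},
            )
            key = (pid, day)
            prev = best.get(key)
            if prev is None:
                best[key] = rec
            else:
                n_dup += 1
                if rec.entry_day < prev.entry_day:
                    best[key] = rec
        records = [best[k] for k in sorted(best)]
        return IngestResult(records, n_rows, n_back, n_dup)


def write_diary(records: Iterable[DiaryRecord], path: str | Path, delimiter: str = ",") -> None:
    """Write diary records in the canonical column order."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(DIARY_COLUMNS)
        for r in sorted(records, key=lambda r: (r.patient_id, r.study_day)):
            writer.writerow(
                [r.patient_id, r.study_day, r.entry_day]
                + [int(getattr(r.symptoms, s)) for s in ALL_SYMPTOMS]
                + [
                    int(r.increased_inhaled_medication),
                    int(r.started_antibiotics),
                    int(r.started_corticosteroids),
                    int(r.contact_scheduled_visit),
                    int(r.contact_unscheduled_visit),
                    int(r.contact_emergency),
                    int(r.contact_hospitalization),
                ]
            )


def write_events(events: Iterable[ExacerbationEvent], path: str | Path, delimiter: str = ",") -> None:
    """Write detected events; censored events have an empty end field.

    Round-trips losslessly through :func:`read_events`.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(EVENT_COLUMNS)
        for e in events:
            writer.writerow(
                [
                    e.patient_id,
                    e.onset_day,
                    "" if e.end_day is None else e.end_day,
                    "" if e.duration_days is None else e.duration_days,
                    int(e.recovery_undetermined),
                    e.censor_reason.value,
                    e.observed_end,
                    e.onset_symptom_count,
                    e.severity_bin,
                ]
                + [int(getattr(e.onset_symptoms, s)) for s in ALL_SYMPTOMS]
            )


def read_events(path: str | Path, delimiter: str | None = None) -> list[ExacerbationEvent]:
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    out: list[ExacerbationEvent] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise SchemaError("event file is empty (no header row)")
        missing = [c for c in EVENT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"event file lacks required columns: {missing}")
        for i, row in enumerate(reader, start=2):
            end = row["end_day"].strip()
            out.append(
                ExacerbationEvent(
                    patient_id=row["patient_id"].strip(),
                    onset_day=_parse_int(row["onset_day"], i, "onset_day"),
                    end_day=None if end == "" else int(end),
                    recovery_undetermined=_parse_flag(
                        row["recovery_undetermined"], i, "recovery_undetermined"
                    ),
                    censor_reason=CensorReason(row["censor_reason"].strip()),
                    observed_end=_parse_int(row["observed_end"], i, "observed_end"),
                    onset_symptoms=SymptomSet(
                        **{s: _parse_flag(row[s], i, s) for s in ALL_SYMPTOMS}
                    ),
                )
            )
    return out


BASELINE_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "bmi",
    "smoking_status",
    "n_comorbidities",
    "mmrc",
    "cat_baseline",
    "fev1_pct",
    "depression",
    "anxiety",
    "prior_moderate_severe_exac",
    "treatment_class",
    "ltot",
    "satisfaction",
]

VISIT_COLUMNS = ["patient_id", "visit", "cat"]


def read_baseline(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read the patient baseline table, indexed by patient_id."""
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str})
    missing = [c for c in BASELINE_COLUMNS if c not in df.columns and c != "satisfaction"]
    if missing:
        raise SchemaError(f"baseline file lacks required columns: {missing}")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"duplicate patient_id values in baseline table: {dups}")
    bad_cat = df[(df["cat_baseline"] < 0) | (df["cat_baseline"] > 40)]
    if len(bad_cat):
        raise SchemaError("cat_baseline outside [0, 40]", row=int(bad_cat.index[0]) + 2,
                          column="cat_baseline")
    return df.set_index("patient_id")


def read_visits(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read the visit-level CAT table (long format)."""
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str})
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"visit file lacks required columns: {missing}")
    bad = df[~df["visit"].isin(["inclusion", "month3", "month6"])]
    if len(bad):
        raise SchemaError(
            f"unknown visit label {bad['visit'].iloc[0]!r}", row=int(bad.index[0]) + 2,
            column="visit",
        )
    return df


def write_table(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write an output table with a stable column order (as given)."""
    df.to_csv(path, sep=delimiter, index=False)
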