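"""Domain types for daily symptom-diary data.

A diary stream is one row per patient-day.  Each day carries seven
dichotomous symptom flags (worse than the patient's baseline: yes/no),
medication-change flags and healthcare-contact flags.  The seven symptoms
split into *major* symptoms -- dyspnea, sputum amount, sputum colour
(purulence) -- and *minor* symptoms -- cough, wheeze, sore throat, cold.
This major/minor split drives the exacerbation criterion used by the
detection stage.

A day with no row is a *missing* day; a row with all symptom flags false
is a *recorded symptom-free* day.  The two are never conflated: absence
of a record is not evidence of recovery, and every downstream rule
(onset, termination, washout, censoring) distinguishes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Iterable, Iterator

MAJOR_SYMPTOMS: tuple[str, ...] = ("dyspnea", "sputum_amount", "sputum_color")
MINOR_SYMPTOMS: tuple[str, ...] = ("cough", "wheeze", "sore_throat", "cold")
ALL_SYMPTOMS: tuple[str, ...] = MAJOR_SYMPTOMS + MINOR_SYMPTOMS

#: maximum allowed lag between the day an entry refers to and the day it
#: was keyed in (patients may back-fill up to three previous days)
BACK_ENTRY_WINDOW_DAYS = 3

#: length of the observation window, in study days
DEFAULT_AVAILABLE_DAYS = 180


@dataclass(frozen=True)
class SymptomSet:
    """The seven worse-than-baseline symptom flags for one patient-day."""

    dyspnea: bool = False
    sputum_amount: bool = False
    sputum_color: bool = False
    cough: bool = False
    wheeze: bool = False
    sore_throat: bool = False
    cold: bool = False

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "SymptomSet":
        names = set(names)
        unknown = names - set(ALL_SYMPTOMS)
        if unknown:
            raise ValueError(f"unknown symptom names: {sorted(unknown)}")
        return cls(**{n: True for n in names})

    def active(self) -> tuple[str, ...]:
        """Names of the flagged symptoms, in canonical order."""
        return tuple(n for n in ALL_SYMPTOMS if getattr(self, n))

    @property
    def n_major(self) -> int:
        return sum(getattr(self, n) for n in MAJOR_SYMPTOMS)

    @property
    def symptom_count(self) -> int:
        return sum(getattr(self, n) for n in ALL_SYMPTOMS)

    @property
    def any(self) -> bool:
        """True if at least one symptom is worse than baseline."""
        return any(getattr(self, n) for n in ALL_SYMPTOMS)


@dataclass(frozen=True)
class DiaryRecord:
    """One patient-day diary observation.

    ``entry_day`` is the study day on which the record was keyed in; the
    app allows back-entry of up to three previous days, so
    ``study_day <= entry_day <= study_day + 3`` after ingestion.
    """

    patient_id: str
    study_day: int
    symptoms: SymptomSet = field(default_factory=SymptomSet)
    increased_inhaled_medication: bool = False
    started_antibiotics: bool = False
    started_corticosteroids: bool = False
    contact_scheduled_visit: bool = False
    contact_unscheduled_visit: bool = False
    contact_emergency: bool = False
    contact_hospitalization: bool = False
    entry_day: int | None = None

    def __post_init__(self):
        if self.study_day < 1:
            raise ValueError(f"study_day must be >= 1, got {self.study_day}")
        if self.entry_day is None:
            object.__setattr__(self, "entry_day", self.study_day)
        if not (self.study_day <= self.entry_day <= self.study_day + BACK_ENTRY_WINDOW_DAYS):
            raise ValueError(
                f"entry_day {self.entry_day} outside back-entry window for "
                f"study_day {self.study_day}"
            )

    @property
    def any_contact(self) -> bool:
        return (
            self.contact_scheduled_visit
            or self.contact_unscheduled_visit
            or self.contact_emergency
            or self.contact_hospitalization
        )

    def contact_types(self) -> frozenset[str]:
        out = set()
        if self.contact_scheduled_visit:
            out.add("scheduled_visit")
        if self.contact_unscheduled_visit:
            out.add("unscheduled_visit")
        if self.contact_emergency:
            out.add("emergency")
        if self.contact_hospitalization:
            out.add("hospitalization")
        return frozenset(out)


class CensorReason(str, Enum):
    """Why an event's recovery could not be determined."""

    NONE = "none"
    MISSING_RECORDS = "missing_records"
    PERSISTED_OVER_30_DAYS = "persisted_over_30_days"
    WINDOW_END = "window_end"


def severity_bin(symptom_count: int) -> str:
    """Severity bin by number of onset symptoms: ``2``, ``3`` or ``4plus``."""
    if symptom_count < 2:
        raise ValueError("an exacerbation onset has at least 2 symptoms")
    if symptom_count == 2:
        return "2"
    if symptom_count == 3:
        return "3"
    return "4plus"


@dataclass(frozen=True)
class ExacerbationEvent:
    """A detected symptom-defined exacerbation episode.

    ``observed_end`` is the last study day that informs the event: the
    recorded end day for complete events, the day before the first
    missing day for record-gap censoring, the last worsened day for
    over-30-day persistence, or the window's final day.  Classification
    (reported / treated) scans contact and medication flags over
    ``[onset_day, observed_end]``.
    """

    patient_id: str
    onset_day: int
    end_day: int | None
    recovery_undetermined: bool
    censor_reason: CensorReason
    onset_symptoms: SymptomSet
    observed_end: int

    def __post_init__(self):
        if self.onset_symptoms.n_major < 1 or self.onset_symptoms.symptom_count < 2:
            raise ValueError(
                "onset symptoms must include >=1 major symptom and >=2 symptoms total"
            )
        if self.recovery_undetermined:
            if self.end_day is not None:
                raise ValueError("censored events have no end_day")
            if self.censor_reason is CensorReason.NONE:
                raise ValueError("censored events need a censor_reason")
        else:
            if self.end_day is None or self.censor_reason is not CensorReason.NONE:
                raise ValueError("complete events have an end_day and censor_reason 'none'")
            if self.end_day < self.onset_day + 1:
                raise ValueError("a complete event spans at least 2 days")
        if self.observed_end < self.onset_day:
            raise ValueError("observed_end precedes onset_day")

    @property
    def duration_days(self) -> int | None:
        """Inclusive duration (end - onset + 1); None while censored."""
        if self.end_day is None:
            return None
        return self.end_day - self.onset_day + 1

    @property
    def onset_symptom_count(self) -> int:
        return self.onset_symptoms.symptom_count

    @property
    def severity_bin(self) -> str:
        return severity_bin(self.onset_symptom_count)


@dataclass(frozen=True)
class PatientBaseline:
    """Baseline (inclusion-visit) characteristics of one patient."""

    patient_id: str
    sex: str
    age: float
    bmi: float
    smoking_status: str  # "active" | "former"
    n_comorbidities: int
    mmrc: int
    cat_baseline: int
    fev1_pct: float
    depression: bool = False
    anxiety: bool = False
    prior_moderate_severe_exac: int = 0
    treatment_class: str = ""
    ltot: bool = False
    satisfaction: float | None = None

    def __post_init__(self):
        if not (0 <= self.cat_baseline <= 40):
            raise ValueError("CAT score must lie in [0, 40]")
        if self.fev1_pct <= 0:
            raise ValueError("FEV1 percent predicted must be positive")
        if not (0 <= self.mmrc <= 4):
            raise ValueError("mMRC grade must lie in [0, 4]")
        if min(self.n_comorbidities, self.prior_moderate_severe_exac) < 0:
            raise ValueError("counts must be non-negative")
        if self.smoking_status not in ("active", "former"):
            raise ValueError("smoking_status must be 'active' or 'former'")


VISIT_NAMES = ("inclusion", "month3", "month6")


@dataclass(frozen=True)
class VisitRecord:
    """A CAT health-status score measured at a scheduled study visit."""

    patient_id: str
    visit: str  # "inclusion" | "month3" | "month6"
    cat: int

    def __post_init__(self):
        if self.visit not in VISIT_NAMES:
            raise ValueError(f"visit must be one of {VISIT_NAMES}")
        if not (0 <= self.cat <= 40):
            raise ValueError("CAT score must lie in [0, 40]")


def group_by_patient(records: Iterable[DiaryRecord]) -> dict[str, list[DiaryRecord]]:
    """Group records by patient, each list sorted by study day."""
    out: dict[str, list[DiaryRecord]] = {}
    for r in records:
        out.setdefault(r.patient_id, []).append(r)
    for pid in out:
        out[pid].sort(key=lambda r: r.study_day)
    return out
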