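"""Shared helpers: compact diary-stream builders for detection tests.

Streams are written as one character per study day:

* ``.`` -- recorded symptom-free day
* ``_`` -- missing day (no record)
* ``C`` -- criterion day (dyspnea + cough: one major, two symptoms)
* ``M`` -- major symptom alone (dyspnea): worsened but not a criterion day
* ``m`` -- minor symptom alone (cough): worsened but not a criterion day
"""

from __future__ import annotations

import numpy as np
import pytest

from exadiary.records import ALL_SYMPTOMS, DiaryRecord, SymptomSet

_CHAR_SYMPTOMS = {
    ".": SymptomSet(),
    "C": SymptomSet(dyspnea=True, cough=True),
    "M": SymptomSet(dyspnea=True),
    "m": SymptomSet(cough=True),
}


def stream(pattern: str, patient_id: str = "P1", **day_flags) -> list[DiaryRecord]:
    """Build a diary stream from a day-per-character pattern.

    ``day_flags`` maps a study day to extra DiaryRecord fields, e.g.
    ``stream("CC..", **{"3": {"contact_emergency": True}})``.
    """
    records = []
    for i, ch in enumerate(pattern, start=1):
        if ch == "_":
            continue
        extra = day_flags.get(str(i), {})
        records.append(
            DiaryRecord(patient_id=patient_id, study_day=i,
                        symptoms=_CHAR_SYMPTOMS[ch], **extra)
        )
    return records


def random_stream(
    rng: np.random.Generator,
    n_days: int = 40,
    p_missing: float = 0.3,
    p_symptom: float = 0.25,
    patient_id: str = "P1",
) -> list[DiaryRecord]:
    """Random diary stream with independent per-day, per-symptom flags."""
    records = []
    for d in range(1, n_days + 1):
        if rng.random() < p_missing:
            continue
        flags = {s: bool(rng.random() < p_symptom) for s in ALL_SYMPTOMS}
        records.append(
            DiaryRecord(patient_id=patient_id, study_day=d, symptoms=SymptomSet(**flags))
        )
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
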