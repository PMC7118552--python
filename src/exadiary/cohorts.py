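"""Event-level reconstruction of a published reference cohort (synthetic).

A multicentre smartphone-diary study of 116 frequent-exacerbator COPD
patients followed for 6 months observed 262 symptom-defined
exacerbations and published the event counts by reporting status,
severity bin and treatment category, plus the per-patient event-count
distribution.  The raw diaries were not deposited, so this module
rebuilds a *synthetic* event-level table whose marginal counts equal the
published ones exactly.  It exists so the tabulation and categorisation
stages can be exercised against known printed totals; joint structure
beyond the published margins (which symptoms co-occur in which event,
which patient owns which event) is assigned deterministically and is
not data.
"""

from __future__ import annotations

import numpy as np

from .classification import ClassifiedEvent, TreatmentCategory
from .records import CensorReason, ExacerbationEvent, SymptomSet

# published margins: 262 events, 163 unreported / 99 reported
N_UNREPORTED = 163
N_REPORTED = 99

# events by onset-symptom-count bin (2 / 3 / >=4), per reporting status
SEVERITY_COUNTS = {
    "unreported": {2: 68, 3: 60, 4: 35},
    "reported": {2: 17, 3: 36, 4: 46},
}

# treatment-category counts, per reporting status ("none" = untreated)
TREATMENT_COUNTS = {
    "unreported": {
        TreatmentCategory.BRONCHODILATOR_INCREASE_ONLY: 57,
        TreatmentCategory.ANTIBIOTICS_ONLY: 10,
        TreatmentCategory.CORTICOSTEROIDS_ONLY: 9,
        TreatmentCategory.ANTIBIOTICS_PLUS_CORTICOSTEROIDS: 0,
        TreatmentCategory.NONE: 87,
    },
    "reported": {
        TreatmentCategory.BRONCHODILATOR_INCREASE_ONLY: 15,
        TreatmentCategory.ANTIBIOTICS_ONLY: 47,
        TreatmentCategory.CORTICOSTEROIDS_ONLY: 9,
        TreatmentCategory.ANTIBIOTICS_PLUS_CORTICOSTEROIDS: 28,
        TreatmentCategory.NONE: 0,
    },
}

# per-patient event-count distribution over the 116 patients: 18 with no
# events, 26 with one, 25 with two and 47 with more than two; the >2
# group is split 2 x 3 + 45 x 4 so the total equals 262
PATIENT_EVENT_COUNTS = [0] * 18 + [1] * 26 + [2] * 25 + [3] * 2 + [4] * 45

# duration medians (IQR): unreported 5 (3-8), reported 8 (6-11)
_DURATIONS = {
    "unreported": [3, 4, 5, 8, 9],
    "reported": [6, 7, 8, 11, 12],
}

_SYMPTOM_FILL = ("cough", "cold", "wheeze", "sore_throat", "sputum_amount", "sputum_color")


def _symptoms_for_count(count: int, i: int) -> SymptomSet:
    """Deterministic symptom set with the requested count and >=1 major."""
    majors = ["dyspnea", "sputum_amount", "sputum_color"]
    names = [majors[i % 3]]
    for s in _SYMPTOM_FILL:
        if len(names) >= count:
            break
        if s not in names:
            names.append(s)
    return SymptomSet.from_names(names[:count])


def reference_event_table() -> list[ClassifiedEvent]:
    """The 262-event reconstruction as classified events.

    Counts by reporting status, severity bin and treatment category
    match the published margins exactly; durations cycle through short
    lists reproducing each group's median.
    """
    events: list[ClassifiedEvent] = []
    patient_of_event: list[str] = []
    for p_idx, k in enumerate(PATIENT_EVENT_COUNTS):
        patient_of_event.extend([f"R{p_idx + 1:03d}"] * k)
    # unreported events first, then reported, in deterministic order
    order = ["unreported", "reported"]
    ev_idx = 0
    for status in order:
        reported = status == "reported"
        sev_pool = [c for c, n in SEVERITY_COUNTS[status].items() for _ in range(n)]
        cat_pool = [c for c, n in TREATMENT_COUNTS[status].items() for _ in range(n)]
        durations = _DURATIONS[status]
        for j, (count, category) in enumerate(zip(sev_pool, cat_pool)):
            pid = patient_of_event[ev_idx]
            duration = durations[j % len(durations)]
            onset = 10
            event = ExacerbationEvent(
                patient_id=pid,
                onset_day=onset,
                end_day=onset + duration - 1,
                recovery_undetermined=False,
                censor_reason=CensorReason.NONE,
                onset_symptoms=_symptoms_for_count(min(count, 7), j),
                observed_end=onset + duration - 1,
            )
            events.append(
                ClassifiedEvent(
                    event=event,
                    reported=reported,
                    treated=category is not TreatmentCategory.NONE,
                    treatment_category=category,
                    contact_types=frozenset({"unscheduled_visit"}) if reported else frozenset(),
                )
            )
            ev_idx += 1
    return events


def reference_events_by_patient() -> dict[str, list[ClassifiedEvent]]:
    """Reference events grouped per patient (116 patients, 18 event-free)."""
    out: dict[str, list[ClassifiedEvent]] = {
        f"R{i + 1:03d}": [] for i in range(len(PATIENT_EVENT_COUNTS))
    }
    for ev in reference_event_table():
        out[ev.event.patient_id].append(ev)
    return out
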