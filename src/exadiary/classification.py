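"""Classification of detected events and patient-level health-status impact.

An event is **reported** if medical attention was sought -- a scheduled
or unscheduled doctor visit, an emergency-department visit or a hospital
admission -- on any recorded day inside the event window, and
**unreported** otherwise.  It is **treated** if at least one medication
changed (antibiotics, systemic corticosteroids, or an increase in
bronchodilators) inside the same window.  Flags on days outside an event
never create or reclassify events: events are defined purely by
symptoms.

Patients are then partitioned into four exclusive groups -- no
exacerbation, unreported only, reported only, mixed -- and health-status
impact is quantified as the change in CAT score between the inclusion
and month-6 visits, with a rise of >=2 points taken as a clinically
significant deterioration.  Patients below 60% overall compliance are
excluded from the CAT analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .records import ALL_SYMPTOMS as _SYMPTOMS
from .records import DiaryRecord, ExacerbationEvent

#: CAT-score rise counted as a clinically significant deterioration
CAT_MCID = 2

#: minimum overall compliance (percent) for the CAT-impact analysis
CAT_COMPLIANCE_THRESHOLD = 60.0


class TreatmentCategory(str, Enum):
    NONE = "none"
    BRONCHODILATOR_INCREASE_ONLY = "bronchodilator_increase_only"
    ANTIBIOTICS_ONLY = "antibiotics_only"
    CORTICOSTEROIDS_ONLY = "corticosteroids_only"
    ANTIBIOTICS_PLUS_CORTICOSTEROIDS = "antibiotics_plus_corticosteroids"
    # reserved for configurations outside the precedence rule (unused by
    # classify_event, which maps every flag combination onto the above)
    OTHER_COMBINATION = "other_combination"


class PatientCategory(str, Enum):
    NO_EXACERBATION = "no_exacerbation"
    UNREPORTED_ONLY = "unreported_only"
    REPORTED_ONLY = "reported_only"
    MIXED = "mixed"


@dataclass(frozen=True)
class ClassifiedEvent:
    """An exacerbation event with reporting and treatment status."""

    event: ExacerbationEvent
    reported: bool
    treated: bool
    treatment_category: TreatmentCategory
    contact_types: frozenset[str]

    def __post_init__(self):
        if self.reported and not self.contact_types:
            raise ValidationError("reported events must carry at least one contact type")
        if self.treated != (self.treatment_category is not TreatmentCategory.NONE):
            raise ValidationError("treated flag inconsistent with treatment_category")


def _treatment_category(broncho: bool, abx: bool, cs: bool) -> TreatmentCategory:
    # precedence: antibiotics+corticosteroids > antibiotics > systemic
    # corticosteroids > bronchodilator increase
    if abx and cs:
        return TreatmentCategory.ANTIBIOTICS_PLUS_CORTICOSTEROIDS
    if abx:
        return TreatmentCategory.ANTIBIOTICS_ONLY
    if cs:
        return TreatmentCategory.CORTICOSTEROIDS_ONLY
    if broncho:
        return TreatmentCategory.BRONCHODILATOR_INCREASE_ONLY
    return TreatmentCategory.NONE


def classify_event(
    event: ExacerbationEvent, records: Sequence[DiaryRecord]
) -> ClassifiedEvent:
    """Attach reporting and treatment status to a detected event.

    Scans contact and medication flags on recorded days within
    ``[onset_day, observed_end]``; for censored events the window closes
    at the last observed in-event day.
    """
    in_window = [
        r
        for r in records
        if r.patient_id == event.patient_id
        and event.onset_day <= r.study_day <= event.observed_end
    ]
    if not any(r.study_day == event.onset_day for r in in_window):
        raise ValidationError(
            f"event onset day {event.onset_day} has no record in the supplied diary"
        )
    contacts: set[str] = set()
    broncho = abx = cs = False
    for r in in_window:
        contacts |= r.contact_types()
        broncho = broncho or r.increased_inhaled_medication
        abx = abx or r.started_antibiotics
        cs = cs or r.started_corticosteroids
    category = _treatment_category(broncho, abx, cs)
    return ClassifiedEvent(
        event=event,
        reported=bool(contacts),
        treated=category is not TreatmentCategory.NONE,
        treatment_category=category,
        contact_types=frozenset(contacts),
    )


def classify_events(
    events: Iterable[ExacerbationEvent], records: Sequence[DiaryRecord]
) -> list[ClassifiedEvent]:
    by_patient: dict[str, list[DiaryRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    return [classify_event(e, by_patient.get(e.patient_id, [])) for e in events]


@dataclass(frozen=True)
class EventTabulation:
    """Event-characteristics tables by reporting status.

    ``summary`` mirrors the usual cohort report shape: duration
    order statistics (complete events only), onset symptom-count mean
    and SD, per-symptom prevalence and severity bins, with counts and
    both column-wise and row-wise percentages.  ``treatment`` breaks
    events down by treatment category within reporting status.
    """

    summary: pd.DataFrame
    treatment: pd.DataFrame
    n_events: int
    n_reported: int
    n_unreported: int

    def share(self, reported: bool | None = None) -> float:
        """Percent of events that are reported (True) or unreported (False)."""
        n = self.n_reported if reported else self.n_unreported
        return 100.0 * n / self.n_events

    def treatment_share(self, category: TreatmentCategory, reported: bool) -> float:
        """Percent of reported/unreported events in a treatment category."""
        col = "reported" if reported else "unreported"
        total = self.n_reported if reported else self.n_unreported
        n = self.treatment.loc[category.value, col] if category.value in self.treatment.index else 0
        return 100.0 * n / total

    def treated_share(self, reported: bool) -> float:
        col = "reported" if reported else "unreported"
        total = self.n_reported if reported else self.n_unreported
        untreated = (
            self.treatment.loc[TreatmentCategory.NONE.value, col]
            if TreatmentCategory.NONE.value in self.treatment.index
            else 0
        )
        return 100.0 * (total - untreated) / total


def tabulate_events(classified: Sequence[ClassifiedEvent]) -> EventTabulation:
    """Characteristics of unreported vs reported exacerbations."""
    if not classified:
        raise ValidationError("no events to tabulate")
    df = pd.DataFrame(
        {
            "reported": [c.reported for c in classified],
            "duration": [c.event.duration_days for c in classified],
            "censored": [c.event.recovery_undetermined for c in classified],
            "n_symptoms": [c.event.onset_symptom_count for c in classified],
            "severity": [c.event.severity_bin for c in classified],
            "treatment": [c.treatment_category.value for c in classified],
            **{
                s: [getattr(c.event.onset_symptoms, s) for c in classified]
                for s in _SYMPTOMS
            },
        }
    )
    n_total = len(df)
    n_rep = int(df["reported"].sum())
    n_unrep = n_total - n_rep

    rows = []
    groups = {
        "global": df,
        "unreported": df[~df["reported"]],
        "reported": df[df["reported"]],
    }
    # duration: complete events only (censored events have no duration)
    for name, g in groups.items():
        dur = g.loc[~g["censored"], "duration"].dropna()
        rows.append(
            {
                "characteristic": "duration_days",
                "group": name,
                "n": len(dur),
                "median": float(dur.median()) if len(dur) else np.nan,
                "q25": float(dur.quantile(0.25)) if len(dur) else np.nan,
                "q75": float(dur.quantile(0.75)) if len(dur) else np.nan,
            }
        )
    for name, g in groups.items():
        rows.append(
            {
                "characteristic": "onset_symptom_count",
                "group": name,
                "n": len(g),
                "mean": float(g["n_symptoms"].mean()),
                "sd": float(g["n_symptoms"].std(ddof=1)) if len(g) > 1 else np.nan,
            }
        )
    for s in _SYMPTOMS:
        for name, g in groups.items():
            n = int(g[s].sum())
            rows.append(
                {
                    "characteristic": f"symptom_{s}",
                    "group": name,
                    "n": n,
                    "column_pct": 100.0 * n / len(g) if len(g) else np.nan,
                }
            )
    for sev in ("2", "3", "4plus"):
        sub = df[df["severity"] == sev]
        for name, g in groups.items():
            gs = g[g["severity"] == sev]
            rows.append(
                {
                    "characteristic": f"severity_{sev}",
                    "group": name,
                    "n": len(gs),
                    "column_pct": 100.0 * len(gs) / len(g) if len(g) else np.nan,
                    "row_pct": 100.0 * len(gs) / len(sub) if len(sub) else np.nan,
                }
            )
    summary = pd.DataFrame(rows)

    treatment = (
        df.groupby(["treatment", "reported"]).size().unstack(fill_value=0)
    )
    treatment.columns = ["reported" if c else "unreported" for c in treatment.columns]
    for col in ("unreported", "reported"):
        if col not in treatment:
            treatment[col] = 0
    treatment = treatment[["unreported", "reported"]]
    treatment["unreported_pct"] = 100.0 * treatment["unreported"] / max(n_unrep, 1)
    treatment["reported_pct"] = 100.0 * treatment["reported"] / max(n_rep, 1)
    treatment.index.name = "treatment_category"

    return EventTabulation(summary, treatment, n_total, n_rep, n_unrep)


@dataclass(frozen=True)
class CatImpactResult:
    """Patient categorisation plus CAT-change group tests.

    ``table`` has one row per patient; the Kruskal-Wallis test compares
    CAT change across the exacerbation categories among eligible
    patients with both visit scores, and the chi-square test compares
    the proportions with a >=2-point deterioration.  Either test is
    ``None`` when the corresponding contingency degenerates (fewer than
    two non-empty groups, or a zero margin).
    """

    table: pd.DataFrame
    kruskal_cat_change: object | None
    chi2_mcid: object | None


def categorize_patients(
    events_by_patient: Mapping[str, Sequence[ClassifiedEvent]],
    compliance: pd.DataFrame,
    visits: pd.DataFrame | None = None,
) -> CatImpactResult:
    """Four-group patient categorisation and CAT-change impact.

    ``compliance`` is the per-patient table from
    :func:`exadiary.compliance.summarize_cohort` (one row per patient);
    it defines the patient universe.  ``visits`` is the long visit table
    with inclusion / month6 CAT scores; patients missing either score
    keep ``cat_change`` empty and drop out of the group tests only.
    """
    from .model import chi_square_test  # local import to avoid a cycle

    comp = compliance.set_index("patient_id") if "patient_id" in compliance else compliance
    if comp.index.duplicated().any():
        raise ValidationError("one compliance summary per patient is required")

    cat_by_visit: dict[str, dict[str, int]] = {}
    if visits is not None:
        for _, row in visits.iterrows():
            cat_by_visit.setdefault(str(row["patient_id"]), {})[row["visit"]] = int(row["cat"])

    rows = []
    for pid in comp.index:
        evs = list(events_by_patient.get(pid, []))
        any_rep = any(c.reported for c in evs)
        any_unrep = any(not c.reported for c in evs)
        if not evs:
            cat = PatientCategory.NO_EXACERBATION
        elif any_rep and any_unrep:
            cat = PatientCategory.MIXED
        elif any_rep:
            cat = PatientCategory.REPORTED_ONLY
        else:
            cat = PatientCategory.UNREPORTED_ONLY
        eligible = comp.loc[pid, "overall_compliance"] >= CAT_COMPLIANCE_THRESHOLD
        scores = cat_by_visit.get(pid, {})
        change = (
            scores["month6"] - scores["inclusion"]
            if "month6" in scores and "inclusion" in scores
            else None
        )
        rows.append(
            {
                "patient_id": pid,
                "n_events": len(evs),
                "n_reported": sum(c.reported for c in evs),
                "n_unreported": sum(not c.reported for c in evs),
                "category": cat.value,
                "eligible_for_cat_analysis": bool(eligible),
                "cat_change": change,
                "cat_deterioration_mcid": (change is not None and change >= CAT_MCID),
            }
        )
    table = pd.DataFrame(rows)

    analysed = table[
        table["eligible_for_cat_analysis"] & table["cat_change"].notna()
    ]
    kw = chi2 = None
    present = analysed["category"].unique()
    if len(present) >= 2:
        from .compliance import compare_groups

        kw = compare_groups(
            analysed["cat_change"].astype(float).to_numpy(),
            analysed["category"].to_numpy(),
        )
        counts = (
            analysed.groupby(["cat_deterioration_mcid", "category"])
            .size()
            .unstack(fill_value=0)
        )
        try:
            chi2 = chi_square_test(counts.to_numpy())
        except ValidationError:
            chi2 = None
    return CatImpactResult(table, kw, chi2)
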