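"""Event classification, tabulation and patient-level CAT impact."""

import numpy as np
import pandas as pd
import pytest

from exadiary.classification import (
    TreatmentCategory,
    categorize_patients,
    classify_event,
    classify_events,
    tabulate_events,
)
from exadiary.cohorts import reference_event_table, reference_events_by_patient
from exadiary.compliance import summarize_cohort
from exadiary.detection import detect_events
from exadiary.errors import ValidationError

from conftest import stream


def _event(records, n_days):
    events = detect_events(records, n_days=n_days)
    assert len(events) == 1
    return events[0]


class TestClassifyEvent:
    def test_contact_inside_window_marks_reported(self):
        records = stream(
            "..CCCC....", **{"5": {"contact_unscheduled_visit": True}}
        )
        ev = _event(records, 10)
        c = classify_event(ev, records)
        assert c.reported and c.contact_types == frozenset({"unscheduled_visit"})

    def test_no_flags_means_unreported_untreated(self):
        records = stream("..CCCC....")
        c = classify_event(_event(records, 10), records)
        assert not c.reported and not c.treated
        assert c.treatment_category is TreatmentCategory.NONE

    def test_bronchodilator_increase_is_self_treatment(self):
        records = stream(
            "..CCCC....", **{"4": {"increased_inhaled_medication": True}}
        )
        c = classify_event(_event(records, 10), records)
        assert not c.reported and c.treated
        assert c.treatment_category is TreatmentCategory.BRONCHODILATOR_INCREASE_ONLY

    @pytest.mark.parametrize(
        "flags, expected",
        [
            ({"started_antibiotics": True}, TreatmentCategory.ANTIBIOTICS_ONLY),
            ({"started_corticosteroids": True}, TreatmentCategory.CORTICOSTEROIDS_ONLY),
            (
                {"started_antibiotics": True, "started_corticosteroids": True},
                TreatmentCategory.ANTIBIOTICS_PLUS_CORTICOSTEROIDS,
            ),
            (
                {"started_antibiotics": True, "increased_inhaled_medication": True},
                TreatmentCategory.ANTIBIOTICS_ONLY,  # precedence over bronchodilator
            ),
        ],
    )
    def test_treatment_precedence(self, flags, expected):
        records = stream("..CCCC....", **{"4": flags})
        assert classify_event(_event(records, 10), records).treatment_category is expected

    def test_flags_outside_event_window_are_ignored(self):
        records = stream(
            "..CCCC....",
            **{"9": {"contact_emergency": True, "started_antibiotics": True}},
        )
        c = classify_event(_event(records, 10), records)
        assert not c.reported and not c.treated

    def test_censored_event_classified_up_to_observed_end(self):
        records = stream(
            "..CCC_....", **{"5": {"contact_hospitalization": True}}
        )
        ev = _event(records, 10)
        assert ev.recovery_undetermined
        assert classify_event(ev, records).reported


class TestTabulateEvents:
    def test_median_iqr_from_hand_sorted_durations(self):
        durations = [2, 3, 4, 5, 6, 7, 8, 9, 10, 20]
        records, events = [], []
        for i, d in enumerate(durations):
            recs = stream("." + "C" * d + "...", patient_id=f"P{i}")
            records += recs
            events += detect_events(recs, n_days=d + 4)
        tab = tabulate_events(classify_events(events, records))
        row = tab.summary[
            (tab.summary["characteristic"] == "duration_days")
            & (tab.summary["group"] == "global")
        ].iloc[0]
        assert row["median"] == 6.5  # mean of 5th/6th order statistics
        assert row["q25"] == 4.25 and row["q75"] == 8.75

    def test_single_event_lands_in_its_severity_cell(self):
        records = stream("..CCCC....")
        tab = tabulate_events(classify_events(detect_events(records, 10), records))
        row = tab.summary[
            (tab.summary["characteristic"] == "severity_2")
            & (tab.summary["group"] == "unreported")
        ].iloc[0]
        assert row["n"] == 1 and row["column_pct"] == 100.0

    def test_empty_event_list_rejected(self):
        with pytest.raises(ValidationError):
            tabulate_events([])

    def test_reference_cohort_reproduces_printed_shares(self):
        tab = tabulate_events(reference_event_table())
        assert tab.n_events == 262
        assert round(tab.share(reported=False), 1) == 62.2
        assert round(tab.treated_share(reported=False), 1) == 46.6
        assert round(
            tab.treatment_share(TreatmentCategory.ANTIBIOTICS_ONLY, reported=True), 1
        ) == 47.5
        assert round(
            tab.treatment_share(
                TreatmentCategory.BRONCHODILATOR_INCREASE_ONLY, reported=False
            ),
            1,
        ) == 35.0
        # duration medians by reporting status
        s = tab.summary.set_index(["characteristic", "group"])
        assert s.loc[("duration_days", "unreported"), "median"] == 5
        assert s.loc[("duration_days", "reported"), "median"] == 8

    def test_reported_and_unreported_counts_partition(self):
        tab = tabulate_events(reference_event_table())
        assert tab.n_reported + tab.n_unreported == tab.n_events


class TestCategorizePatients:
    def _compliance(self, pids, pct):
        return pd.DataFrame(
            {"patient_id": pids, "overall_compliance": [pct] * len(pids)}
        )

    def test_four_group_partition_and_eligibility(self):
        by_patient = reference_events_by_patient()
        comp = self._compliance(list(by_patient), 80.0)
        res = categorize_patients(by_patient, comp)
        t = res.table
        assert len(t) == 116
        assert (t["n_events"] == 0).sum() == 18
        assert set(t["category"]) <= {
            "no_exacerbation", "unreported_only", "reported_only", "mixed"
        }
        assert (t.loc[t["n_events"] == 0, "category"] == "no_exacerbation").all()
        mixed = t[t["category"] == "mixed"]
        assert ((mixed["n_reported"] >= 1) & (mixed["n_unreported"] >= 1)).all()

    def test_low_compliance_excluded_from_cat_analysis(self):
        by_patient = reference_events_by_patient()
        comp = self._compliance(list(by_patient), 50.0)
        res = categorize_patients(by_patient, comp)
        assert not res.table["eligible_for_cat_analysis"].any()

    def test_cat_change_and_mcid_flag(self):
        by_patient = {"P1": [], "P2": []}
        comp = self._compliance(["P1", "P2"], 90.0)
        visits = pd.DataFrame(
            {
                "patient_id": ["P1", "P1", "P2"],
                "visit": ["inclusion", "month6", "inclusion"],
                "cat": [10, 13, 20],
            }
        )
        res = categorize_patients(by_patient, comp, visits)
        t = res.table.set_index("patient_id")
        assert t.loc["P1", "cat_change"] == 3
        assert bool(t.loc["P1", "cat_deterioration_mcid"])
        assert pd.isna(t.loc["P2", "cat_change"])  # month6 missing
        assert not bool(t.loc["P2", "cat_deterioration_mcid"])

    def test_duplicate_compliance_rows_rejected(self):
        comp = self._compliance(["P1", "P1"], 90.0)
        with pytest.raises(ValidationError):
            categorize_patients({"P1": []}, comp)
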