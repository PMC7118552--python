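"""Per-patient diary-compliance metrics and stratified group comparisons.

Two metrics summarise how faithfully a patient kept the daily diary over
the fixed study window (180 available days by default; hospitalisation
days count as available days):

* **overall compliance** -- distinct recorded days as a percentage of
  available days;
* **duration compliance** -- the inclusive span from first to last
  recorded day as a percentage of available days.

Overall compliance can never exceed duration compliance, since every
recorded day lies inside the recorded span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .records import DEFAULT_AVAILABLE_DAYS, DiaryRecord, group_by_patient

#: study-time months are 30-day blocks (patients enrol on different dates)
MONTH_LENGTH_DAYS = 30

#: exact Mann-Whitney enumeration is used when both groups are at most
#: this large and the data are tie-free
EXACT_MW_MAX_N = 8


def _recorded_days(records: Iterable[DiaryRecord] | Iterable[int]) -> set[int]:
    days = set()
    for r in records:
        days.add(r.study_day if isinstance(r, DiaryRecord) else int(r))
    return days


def overall_compliance(
    records: Iterable[DiaryRecord] | Iterable[int],
    available_days: int = DEFAULT_AVAILABLE_DAYS,
) -> float:
    """Percentage of available days with a diary record."""
    if available_days <= 0:
        raise ValidationError("available_days must be positive")
    return 100.0 * len(_recorded_days(records)) / available_days


def duration_compliance(
    records: Iterable[DiaryRecord] | Iterable[int],
    available_days: int = DEFAULT_AVAILABLE_DAYS,
) -> float:
    """Inclusive first-to-last-record span as a percentage of available days."""
    if available_days <= 0:
        raise ValidationError("available_days must be positive")
    days = _recorded_days(records)
    if not days:
        return 0.0
    return 100.0 * (max(days) - min(days) + 1) / available_days


def discontinuation_month(
    records: Iterable[DiaryRecord] | Iterable[int],
    available_days: int = DEFAULT_AVAILABLE_DAYS,
    grace_days: int = 0,
) -> int | None:
    """30-day-block month of the last record, for patients who stopped early.

    Returns ``None`` when records extend to within ``grace_days`` of the
    window end (the patient never abandoned the diary).  A patient with
    no records at all is assigned month 1 (never started).
    """
    days = _recorded_days(records)
    if not days:
        return 1
    last = max(days)
    if last >= available_days - grace_days:
        return None
    return math.ceil(last / MONTH_LENGTH_DAYS)


@dataclass(frozen=True)
class ComplianceSummary:
    """Compliance metrics for one patient."""

    patient_id: str
    days_recorded: int
    available_days: int
    overall_compliance: float
    first_day: int | None
    last_day: int | None
    duration_compliance: float
    discontinued_month: int | None
    never_started: bool


def summarize_patient(
    patient_id: str,
    records: Sequence[DiaryRecord] | Sequence[int],
    available_days: int = DEFAULT_AVAILABLE_DAYS,
) -> ComplianceSummary:
    days = _recorded_days(records)
    return ComplianceSummary(
        patient_id=patient_id,
        days_recorded=len(days),
        available_days=available_days,
        overall_compliance=overall_compliance(days, available_days),
        first_day=min(days) if days else None,
        last_day=max(days) if days else None,
        duration_compliance=duration_compliance(days, available_days),
        discontinued_month=discontinuation_month(days, available_days),
        never_started=not days,
    )


def summarize_cohort(
    records: Iterable[DiaryRecord],
    patient_ids: Iterable[str] | None = None,
    available_days: int = DEFAULT_AVAILABLE_DAYS,
) -> pd.DataFrame:
    """Per-patient compliance table over a mixed diary stream.

    ``patient_ids`` may list patients with zero records (e.g. from the
    baseline table) so that never-starters appear in the summary.
    """
    grouped = group_by_patient(records)
    pids = sorted(set(grouped) | set(patient_ids or ()))
    rows = [summarize_patient(pid, grouped.get(pid, []), available_days) for pid in pids]
    return pd.DataFrame([vars(s) for s in rows])


@dataclass(frozen=True)
class GroupComparison:
    """Nonparametric comparison of a metric across patient strata."""

    test: str  # "mann-whitney" | "kruskal-wallis"
    statistic: float
    p_value: float
    group_stats: pd.DataFrame  # index: group label; columns: n, median, q25, q75


def compare_groups(values: Sequence[float], groups: Sequence) -> GroupComparison:
    """Compare a per-patient metric across 2 or more strata.

    Two groups: Mann-Whitney rank-sum, exact enumeration when both
    groups have n <= 8 and the pooled data are tie-free, otherwise the
    tie-corrected normal approximation (no continuity correction).
    More than two groups: Kruskal-Wallis H with tie correction.
    Two-sided p-values throughout.
    """
    values = np.asarray(values, dtype=float)
    labels = pd.Series(list(groups))
    if len(values) != len(labels):
        raise ValidationError("values and groups must have equal length")
    by_group = {g: values[(labels == g).to_numpy()] for g in labels.unique()}
    if len(by_group) < 2:
        raise ValidationError("need at least 2 groups")
    for g, v in by_group.items():
        if len(v) == 0:
            raise ValidationError(f"group {g!r} is empty")

    stats_df = pd.DataFrame(
        {
            g: {
                "n": len(v),
                "median": float(np.median(v)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
            }
            for g, v in by_group.items()
        }
    ).T
    stats_df["n"] = stats_df["n"].astype(int)

    samples = list(by_group.values())
    if len(samples) == 2:
        x, y = samples
        tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if (max(len(x), len(y)) <= EXACT_MW_MAX_N and tie_free) else "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        )
        return GroupComparison("mann-whitney", float(res.statistic), float(res.pvalue), stats_df)
    res = stats.kruskal(*samples)
    return GroupComparison("kruskal-wallis", float(res.statistic), float(res.pvalue), stats_df)


#: default stratification variables for the cohort compliance table,
#: mapping a stratum name to a function of the baseline table that
#: returns per-patient labels (NaN labels are dropped)
DEFAULT_STRATA = {
    "sex": lambda b: b["sex"],
    "age_65": lambda b: np.where(b["age"] >= 65, ">=65", "<65"),
    "smoking_status": lambda b: b["smoking_status"],
    "comorbidities_3": lambda b: np.where(b["n_comorbidities"] >= 3, ">=3", "<3"),
    "mmrc_2": lambda b: np.where(b["mmrc"] >= 2, ">=2", "0-1"),
    "cat_10": lambda b: np.where(b["cat_baseline"] >= 10, ">=10", "<10"),
    "depression": lambda b: np.where(b["depression"].astype(bool), "present", "absent"),
    "anxiety": lambda b: np.where(b["anxiety"].astype(bool), "present", "absent"),
    "fev1_50": lambda b: np.where(b["fev1_pct"] < 50, "<50", ">=50"),
    "ltot": lambda b: np.where(b["ltot"].astype(bool), "treated", "not_treated"),
}


def stratified_comparison(
    summaries: pd.DataFrame,
    baseline: pd.DataFrame,
    strata: Mapping[str, object] | None = None,
    metrics: Sequence[str] = ("overall_compliance", "duration_compliance"),
) -> pd.DataFrame:
    """Compliance medians and nonparametric tests by baseline stratum.

    Produces one row per (stratum, group, metric) with the group median
    and IQR, plus the two-sided p-value of the stratum-level test.
    Strata in which some group would be empty are skipped.  No
    multiple-testing correction is applied.
    """
    if strata is None:
        strata = DEFAULT_STRATA
    summaries = summaries.set_index("patient_id") if "patient_id" in summaries else summaries
    common = summaries.index.intersection(baseline.index)
    rows = []
    for name, fn in strata.items():
        labels = pd.Series(np.asarray(fn(baseline.loc[common])), index=common)
        labels = labels.dropna()
        if labels.nunique() < 2:
            continue
        for metric in metrics:
            vals = summaries.loc[labels.index, metric]
            try:
                cmp = compare_groups(vals.to_numpy(), labels.to_numpy())
            except ValidationError:
                continue
            for g, s in cmp.group_stats.iterrows():
                rows.append(
                    {
                        "stratum": name,
                        "group": g,
                        "metric": metric,
                        "n": int(s["n"]),
                        "median": s["median"],
                        "q25": s["q25"],
                        "q75": s["q75"],
                        "test": cmp.test,
                        "p_value": cmp.p_value,
                    }
                )
    return pd.DataFrame(rows)
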