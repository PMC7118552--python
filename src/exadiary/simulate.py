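"""Synthetic diary-cohort generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: a
cohort of frequent-exacerbator COPD patients keeping a daily symptom
diary over a 180-day window.  Episodes of multi-day symptom worsening
are injected at a configurable rate (default 2.25 per patient per
window), each satisfying the detection criterion (>=1 major plus >=1
further symptom) on every episode day, separated by at least
``washout_min`` symptom-free days.  Whether an episode is *reported*
follows the same two-level logistic law the reporting model estimates:
log-odds increase with episode duration and onset symptom count around
a patient-level random intercept.  Per-patient diary compliance is a
Beta-distributed record propensity (mean ~ 0.67), applied as independent
day-wise record dropout.

The generator returns the full ground truth alongside the degraded
diary, so detection recall/precision, reporting-label recovery and
model parameter recovery can all be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import special

from .detection import is_criterion_day
from .errors import GenerationError, ValidationError
from .records import (
    ALL_SYMPTOMS,
    MAJOR_SYMPTOMS,
    DiaryRecord,
    ExacerbationEvent,
    PatientBaseline,
    SymptomSet,
    VisitRecord,
)

#: re-draw budget for per-episode rejection sampling before giving up
RETRY_LIMIT = 100


class DurationLaw(BaseModel):
    """Episode length in days: ``shift + NegativeBinomial(r, p)``.

    Defaults give a median of 6 days with quartiles 4 and 9, matching
    the symptom-diary event-duration distributions typical of frequent
    exacerbators; the shift enforces the 2-day minimum an event needs to
    satisfy the onset rule.
    """

    shift: int = 2
    r: float = 2.0
    p: float = 0.3

    @model_validator(mode="after")
    def _check(self):
        if self.shift < 2:
            raise ValueError("duration support must start at >= 2 days")
        if not (0 < self.p < 1) or self.r <= 0:
            raise ValueError("invalid negative-binomial parameters")
        return self

    def sample(self, rng: np.random.Generator) -> int:
        return int(self.shift + rng.negative_binomial(self.r, self.p))


class ComplianceLaw(BaseModel):
    """Per-patient record propensity: Beta(a, b), mean a/(a+b) ~ 0.67."""

    a: float = 1.2
    b: float = 0.6

    @model_validator(mode="after")
    def _check(self):
        if min(self.a, self.b) <= 0:
            raise ValueError("Beta parameters must be positive")
        return self

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.a, self.b))


#: per-symptom probability of being active during an episode; chosen to
#: mirror the event-level symptom prevalences of a frequent-exacerbator
#: cohort (sputum amount and cough common, sore throat least so)
DEFAULT_SYMPTOM_PROBS: dict[str, float] = {
    "dyspnea": 0.52,
    "sputum_amount": 0.60,
    "sputum_color": 0.35,
    "cough": 0.62,
    "wheeze": 0.29,
    "sore_throat": 0.22,
    "cold": 0.40,
}

#: treatment-category probabilities conditional on reported status
DEFAULT_TREATMENT_PROBS: dict[str, dict[str, float]] = {
    "reported": {
        "bronchodilator_increase_only": 0.152,
        "antibiotics_only": 0.475,
        "corticosteroids_only": 0.090,
        "antibiotics_plus_corticosteroids": 0.283,
        "none": 0.0,
    },
    "unreported": {
        "bronchodilator_increase_only": 0.350,
        "antibiotics_only": 0.061,
        "corticosteroids_only": 0.055,
        "antibiotics_plus_corticosteroids": 0.0,
        "none": 0.534,
    },
}

#: healthcare-contact type probabilities for reported events
DEFAULT_CONTACT_PROBS: dict[str, float] = {
    "unscheduled_visit": 0.797,
    "emergency": 0.022,
    "hospitalization": 0.181,
}

#: month-6 CAT shift by ground-truth exacerbation category; signs mirror
#: the observed pattern (improvement without events or with reported-only
#: events, deterioration with unreported or mixed events)
DEFAULT_CAT_SHIFT: dict[str, float] = {
    "no_exacerbation": -3.0,
    "unreported_only": 1.0,
    "reported_only": -2.0,
    "mixed": 3.0,
}


class SyntheticCohortConfig(BaseModel):
    """All generator parameters; deterministic given ``seed``."""

    n_patients: int = 116
    n_days: int = 180
    episode_rate: float = 2.25
    duration_law: DurationLaw = Field(default_factory=DurationLaw)
    symptom_inclusion_probs: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_SYMPTOM_PROBS)
    )
    noise_day_prob: float = 0.02
    compliance_law: ComplianceLaw | float = Field(default_factory=ComplianceLaw)
    reporting_intercept: float = -3.15
    beta_duration: float = math.log(1.15)
    beta_symptoms: float = math.log(1.75)
    patient_sd: float = 1.0
    treatment_probs: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TREATMENT_PROBS.items()}
    )
    contact_probs: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_CONTACT_PROBS)
    )
    washout_min: int = 9
    cat_group_shift: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_CAT_SHIFT)
    )
    cat_noise_sd: float = 2.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.n_patients < 1 or self.n_days < 10:
            raise ValueError("cohort must have >=1 patient and >=10 days")
        if self.episode_rate < 0:
            raise ValueError("episode_rate must be >= 0")
        if self.washout_min < 7:
            raise ValueError("washout_min must be >= 7 (the detection washout)")
        if not (0.0 <= self.noise_day_prob <= 1.0):
            raise ValueError("noise_day_prob must lie in [0, 1]")
        if set(self.symptom_inclusion_probs) != set(ALL_SYMPTOMS):
            raise ValueError("symptom_inclusion_probs must cover all seven symptoms")
        for v in self.symptom_inclusion_probs.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError("symptom probabilities must lie in [0, 1]")
        if isinstance(self.compliance_law, float) and not (0.0 <= self.compliance_law <= 1.0):
            raise ValueError("fixed compliance must lie in [0, 1]")
        for status, probs in self.treatment_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError(f"treatment probabilities for {status!r} must sum to 1")
        if abs(sum(self.contact_probs.values()) - 1.0) > 1e-6:
            raise ValueError("contact probabilities must sum to 1")
        if self.patient_sd < 0:
            raise ValueError("patient_sd must be >= 0")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Simulation truth for recovery scoring.

    ``episodes`` has one row per injected episode: patient_id, onset,
    end, duration, onset symptom set and count, reported flag, contact
    type, treatment category, plus the patient's random intercept.
    ``propensities`` maps patient_id -> record propensity.
    """

    episodes: pd.DataFrame
    propensities: pd.Series
    random_intercepts: pd.Series


@dataclass(frozen=True)
class SyntheticCohort:
    records: list[DiaryRecord]
    full_records: list[DiaryRecord]  # before compliance degradation
    baseline: pd.DataFrame
    visits: pd.DataFrame
    truth: GroundTruth


def _episode_symptoms(probs: Mapping[str, float], rng: np.random.Generator) -> SymptomSet:
    for _ in range(RETRY_LIMIT * 10):
        flags = {s: bool(rng.random() < probs[s]) for s in ALL_SYMPTOMS}
        sset = SymptomSet(**flags)
        if is_criterion_day(sset):
            return sset
    # probabilities so extreme the criterion is essentially unreachable
    return SymptomSet(dyspnea=True, cough=True)


def _place_episodes(
    k: int,
    durations: list[int],
    n_days: int,
    washout: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Non-overlapping (onset, end) pairs separated by >= washout free days.

    The episode count is truncated to what fits in the window after
    ``RETRY_LIMIT`` re-draws of the duration list; an empty window for
    even a single minimal episode raises a generation error.
    """
    if k == 0:
        return []
    if durations and min(durations) > n_days:
        raise GenerationError(
            f"window of {n_days} days cannot hold a single drawn episode "
            f"(shortest drawn duration {min(durations)})"
        )
    # documented truncation: drop trailing episodes until the drawn
    # durations plus mandatory washout gaps fit in the window
    required = sum(durations) + washout * (k - 1)
    while required > n_days and k > 0:
        k -= 1
        durations = durations[:k]
        required = sum(durations) + washout * (k - 1)
    if k == 0:
        return []
    slack = n_days - required
    weights = rng.dirichlet(np.ones(k + 1))
    extra = rng.multinomial(slack, weights)
    spans = []
    day = 1 + int(extra[0])
    for i in range(k):
        onset = day
        end = onset + durations[i] - 1
        spans.append((onset, end))
        day = end + washout + int(extra[i + 1]) + 1
    assert spans[-1][1] <= n_days
    return spans


def _truth_category(reported_flags: Sequence[bool]) -> str:
    if not reported_flags:
        return "no_exacerbation"
    any_rep = any(reported_flags)
    any_unrep = any(not r for r in reported_flags)
    if any_rep and any_unrep:
        return "mixed"
    return "reported_only" if any_rep else "unreported_only"


def _baseline_row(pid: str, rng: np.random.Generator) -> PatientBaseline:
    mmrc = int(rng.choice([0, 1, 2, 3, 4], p=[0.08, 0.15, 0.35, 0.30, 0.12]))
    return PatientBaseline(
        patient_id=pid,
        sex="male" if rng.random() < 0.784 else "female",
        age=float(np.clip(rng.normal(66.5, 8.1), 42, 90)),
        bmi=float(np.clip(rng.normal(27.3, 5.0), 15, 45)),
        smoking_status="active" if rng.random() < 0.138 else "former",
        n_comorbidities=int(rng.poisson(2.6)),
        mmrc=mmrc,
        cat_baseline=int(np.clip(round(rng.normal(14.1, 6.1)), 0, 40)),
        fev1_pct=float(np.clip(rng.normal(44.6, 16.2), 15, 95)),
        depression=bool(rng.random() < 0.06),
        anxiety=bool(rng.random() < 0.18),
        prior_moderate_severe_exac=int(2 + rng.poisson(1.0)),
        treatment_class=str(
            rng.choice(
                ["lama", "lama_laba", "laba_ics", "triple"],
                p=[0.052, 0.319, 0.052, 0.577],
            )
        ),
        ltot=bool(rng.random() < 0.31),
        satisfaction=float(np.clip(round(rng.normal(9.0, 1.5)), 0, 10)),
    )


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate diaries, baseline and visit tables plus ground truth.

    Deterministic given ``config.seed``: the same config yields
    bit-identical output on every run.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    width = len(str(config.n_patients))
    symptom_probs = config.symptom_inclusion_probs
    treatment_cats = {
        status: (list(probs.keys()), np.array(list(probs.values())))
        for status, probs in config.treatment_probs.items()
    }
    contact_names = list(config.contact_probs.keys())
    contact_p = np.array(list(config.contact_probs.values()))

    full_records: list[DiaryRecord] = []
    baseline_rows = []
    visit_rows = []
    truth_rows = []
    propensities = {}
    intercepts = {}

    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        base = _baseline_row(pid, rng)
        baseline_rows.append(vars(base).copy())
        propensity = (
            config.compliance_law
            if isinstance(config.compliance_law, float)
            else config.compliance_law.sample(rng)
        )
        propensities[pid] = propensity
        u_i = float(rng.normal(0.0, config.patient_sd)) if config.patient_sd > 0 else 0.0
        intercepts[pid] = u_i

        k = int(rng.poisson(config.episode_rate))
        durations = [config.duration_law.sample(rng) for _ in range(k)]
        spans = _place_episodes(k, durations, config.n_days, config.washout_min, rng)

        day_symptoms: dict[int, SymptomSet] = {}
        med_flags: dict[int, dict[str, bool]] = {}
        contact_flags: dict[int, str] = {}
        reported_flags: list[bool] = []

        for onset, end in spans:
            sset = _episode_symptoms(symptom_probs, rng)
            duration = end - onset + 1
            for d in range(onset, end + 1):
                day_symptoms[d] = sset
            logit = (
                config.reporting_intercept
                + config.beta_duration * duration
                + config.beta_symptoms * sset.symptom_count
                + u_i
            )
            reported = bool(rng.random() < special.expit(logit))
            reported_flags.append(reported)
            status = "reported" if reported else "unreported"
            cats, cat_p = treatment_cats[status]
            category = str(rng.choice(cats, p=cat_p))
            contact_type = ""
            if reported:
                contact_type = str(rng.choice(contact_names, p=contact_p))
                contact_day = int(rng.integers(onset, end + 1))
                contact_flags[contact_day] = contact_type
            if category != "none":
                med_day = int(rng.integers(onset, end + 1))
                flags = med_flags.setdefault(med_day, {})
                if category == "bronchodilator_increase_only":
                    flags["increased_inhaled_medication"] = True
                if category in ("antibiotics_only", "antibiotics_plus_corticosteroids"):
                    flags["started_antibiotics"] = True
                if category in ("corticosteroids_only", "antibiotics_plus_corticosteroids"):
                    flags["started_corticosteroids"] = True
            truth_rows.append(
                {
                    "patient_id": pid,
                    "onset_day": onset,
                    "end_day": end,
                    "duration_days": duration,
                    "onset_symptoms": ";".join(sset.active()),
                    "onset_symptom_count": sset.symptom_count,
                    "reported": reported,
                    "contact_type": contact_type,
                    "treatment_category": category,
                    "random_intercept": u_i,
                }
            )

        in_episode = set(day_symptoms)
        for d in range(1, config.n_days + 1):
            if d not in in_episode and rng.random() < config.noise_day_prob:
                day_symptoms[d] = SymptomSet.from_names(
                    [str(rng.choice(ALL_SYMPTOMS))]
                )

        for d in range(1, config.n_days + 1):
            sset = day_symptoms.get(d, SymptomSet())
            meds = med_flags.get(d, {})
            contact = contact_flags.get(d)
            full_records.append(
                DiaryRecord(
                    patient_id=pid,
                    study_day=d,
                    symptoms=sset,
                    increased_inhaled_medication=meds.get(
                        "increased_inhaled_medication", False
                    ),
                    started_antibiotics=meds.get("started_antibiotics", False),
                    started_corticosteroids=meds.get("started_corticosteroids", False),
                    contact_scheduled_visit=contact == "scheduled_visit",
                    contact_unscheduled_visit=contact == "unscheduled_visit",
                    contact_emergency=contact == "emergency",
                    contact_hospitalization=contact == "hospitalization",
                )
            )

        category = _truth_category(reported_flags)
        cat0 = base.cat_baseline
        cat3 = int(np.clip(cat0 + round(rng.normal(0.0, config.cat_noise_sd)), 0, 40))
        cat6 = int(
            np.clip(
                cat0
                + config.cat_group_shift[category]
                + round(rng.normal(0.0, config.cat_noise_sd)),
                0,
                40,
            )
        )
        visit_rows.append({"patient_id": pid, "visit": "inclusion", "cat": cat0})
        visit_rows.append({"patient_id": pid, "visit": "month3", "cat": cat3})
        visit_rows.append({"patient_id": pid, "visit": "month6", "cat": cat6})

    degraded = degrade_compliance(
        full_records, propensities, seed=int(rng.integers(0, 2**31 - 1))
    )
    truth = GroundTruth(
        episodes=pd.DataFrame(
            truth_rows,
            columns=[
                "patient_id", "onset_day", "end_day", "duration_days",
                "onset_symptoms", "onset_symptom_count", "reported",
                "contact_type", "treatment_category", "random_intercept",
            ],
        ),
        propensities=pd.Series(propensities, name="propensity"),
        random_intercepts=pd.Series(intercepts, name="random_intercept"),
    )
    baseline = pd.DataFrame(baseline_rows).set_index("patient_id")
    visits = pd.DataFrame(visit_rows)
    return SyntheticCohort(degraded, full_records, baseline, visits, truth)


def degrade_compliance(
    records: Iterable[DiaryRecord],
    propensities: Mapping[str, float] | float,
    seed: int,
) -> list[DiaryRecord]:
    """Independently retain each record with its patient's propensity.

    Kept separate from generation so tests can compare the full and
    degraded streams for the same cohort.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = []
    for r in records:
        p = propensities if isinstance(propensities, (int, float)) else propensities[r.patient_id]
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"propensity {p} outside [0, 1]")
        if p >= 1.0 or rng.random() < p:
            out.append(r)
    return out


def recovery_scores(
    events_by_patient: Mapping[str, Sequence[ExacerbationEvent]],
    truth: GroundTruth,
) -> tuple[float, float]:
    """Detection (recall, precision) against injected episodes.

    A detected event matches a truth episode when patient and onset day
    coincide.  Returns (recall, precision); both are 1.0 when the
    generator ran at full compliance with zero noise.
    """
    truth_keys = {
        (row.patient_id, row.onset_day) for row in truth.episodes.itertuples()
    }
    detected_keys = {
        (pid, e.onset_day)
        for pid, events in events_by_patient.items()
        for e in events
    }
    if not truth_keys:
        return (1.0, 1.0 if not detected_keys else 0.0)
    if not detected_keys:
        return (0.0, 1.0)
    hit = len(truth_keys & detected_keys)
    return hit / len(truth_keys), hit / len(detected_keys)
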