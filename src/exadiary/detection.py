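"""Segmentation of diary streams into symptom-defined exacerbation events.

The rule set, operating on one patient's daily records over a fixed
study window (default 180 days):

* **Criterion day** -- a recorded day with at least one major symptom
  (dyspnea, sputum amount, sputum colour) and at least two worsened
  symptoms in total.
* **Onset** -- the first day of the earliest pair of *consecutive
  recorded* criterion days occurring after an eligible washout.  The
  window start is eligible for the first event; thereafter eligibility
  requires >=7 consecutive recorded symptom-free days after the previous
  event resolved.
* **Continuation** -- once begun, the event extends across any recorded
  day with at least one worsened symptom (single-symptom days prolong
  the event even though they would not start one).
* **End** -- the last recorded worsened day followed by two consecutive
  recorded symptom-free days; duration is counted inclusively
  (a minimal event spans 2 days).
* **Censoring** -- recovery is undetermined if a missing day occurs
  before termination is established (``missing_records``), if worsened
  symptoms are still being recorded more than 30 days after onset
  (``persisted_over_30_days``), or if the study window ends first
  (``window_end``).

A missing day is never treated as symptom-free: it cannot serve in the
onset pair, the termination pair, or the washout run.

Two independent implementations are provided.  :func:`detect_events` is
the production single-pass state machine; :func:`brute_force_oracle`
resolves each candidate onset by exhaustive enumeration of termination,
record-gap and persistence points.  Their equivalence on randomized
streams is the module's primary correctness property.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .errors import ValidationError
from .records import (
    DEFAULT_AVAILABLE_DAYS,
    CensorReason,
    DiaryRecord,
    ExacerbationEvent,
    SymptomSet,
)

#: a recorded worsened day more than this many days after onset censors
#: the event as unresolved persistence
PERSISTENCE_LIMIT_DAYS = 30

#: recorded consecutive symptom-free days required between events
WASHOUT_DAYS = 7

_MISSING, _FREE, _WORSE = 0, 1, 2


def is_criterion_day(symptoms: SymptomSet) -> bool:
    """True iff the day meets the exacerbation criterion.

    At least one major symptom (dyspnea, sputum amount or sputum colour)
    plus at least one further symptom, major or minor.
    """
    return symptoms.n_major >= 1 and symptoms.symptom_count >= 2


def _prepare(records: Sequence[DiaryRecord], n_days: int) -> tuple[list[int], list[bool], str | None]:
    """Day-state arrays (1-based; index 0 unused) for one patient."""
    pids = {r.patient_id for r in records}
    if len(pids) > 1:
        raise ValidationError(f"records span multiple patients: {sorted(pids)}")
    state = [_MISSING] * (n_days + 1)
    crit = [False] * (n_days + 1)
    seen: set[int] = set()
    for r in records:
        if r.study_day in seen:
            raise ValidationError(f"duplicate record for study_day {r.study_day}")
        seen.add(r.study_day)
        if r.study_day > n_days:
            raise ValidationError(f"study_day {r.study_day} beyond the {n_days}-day window")
        state[r.study_day] = _WORSE if r.symptoms.any else _FREE
        crit[r.study_day] = is_criterion_day(r.symptoms)
    return state, crit, (pids.pop() if pids else None)


def detect_events(
    records: Sequence[DiaryRecord],
    n_days: int = DEFAULT_AVAILABLE_DAYS,
) -> list[ExacerbationEvent]:
    """Detect exacerbation events in one patient's diary stream.

    Records must be deduplicated and belong to a single patient; output
    events are disjoint, day-ordered and satisfy every event invariant.
    """
    state, crit, pid = _prepare(records, n_days)
    if pid is None:
        return []
    by_day = {r.study_day: r for r in records}
    events: list[ExacerbationEvent] = []

    d = 1
    washout_ok = True  # the window start is an eligible washout
    free_run = 0
    while d <= n_days:
        if not washout_ok:
            if state[d] == _FREE:
                free_run += 1
                if free_run >= WASHOUT_DAYS:
                    washout_ok = True
            else:
                free_run = 0
            d += 1
            continue
        if d + 1 <= n_days and crit[d] and crit[d + 1]:
            event, resume = _follow_event(pid, by_day[d].symptoms, d, state, n_days)
            events.append(event)
            washout_ok = False
            free_run = 0
            d = resume
        else:
            d += 1
    return events


def _follow_event(
    pid: str,
    onset_symptoms: SymptomSet,
    onset: int,
    state: list[int],
    n_days: int,
) -> tuple[ExacerbationEvent, int]:
    """Walk forward from a confirmed onset until the event resolves.

    Returns the event and the day at which outer scanning resumes (for
    complete events, the first of the two terminating symptom-free days,
    so they count towards the next washout).
    """

    def censored(reason: CensorReason, observed_end: int) -> ExacerbationEvent:
        return ExacerbationEvent(
            patient_id=pid,
            onset_day=onset,
            end_day=None,
            recovery_undetermined=True,
            censor_reason=reason,
            onset_symptoms=onset_symptoms,
            observed_end=observed_end,
        )

    def complete(end: int) -> ExacerbationEvent:
        return ExacerbationEvent(
            patient_id=pid,
            onset_day=onset,
            end_day=end,
            recovery_undetermined=False,
            censor_reason=CensorReason.NONE,
            onset_symptoms=onset_symptoms,
            observed_end=end,
        )

    last_worse = onset + 1  # the second onset day is a criterion (hence worsened) day
    d = onset + 2
    while True:
        if d > n_days:
            return censored(CensorReason.WINDOW_END, n_days), n_days + 1
        s = state[d]
        if s == _MISSING:
            return censored(CensorReason.MISSING_RECORDS, d - 1), d + 1
        if s == _WORSE:
            if d - onset > PERSISTENCE_LIMIT_DAYS:
                return censored(CensorReason.PERSISTED_OVER_30_DAYS, d), d + 1
            last_worse = d
            d += 1
            continue
        # recorded symptom-free day: termination needs a second one
        if d + 1 > n_days:
            return censored(CensorReason.WINDOW_END, n_days), n_days + 1
        s2 = state[d + 1]
        if s2 == _FREE:
            return complete(last_worse), d  # resume on the first free day
        if s2 == _MISSING:
            return censored(CensorReason.MISSING_RECORDS, d), d + 2
        # symptoms resumed after a single free day: event continues
        if d + 1 - onset > PERSISTENCE_LIMIT_DAYS:
            return censored(CensorReason.PERSISTED_OVER_30_DAYS, d + 1), d + 2
        last_worse = d + 1
        d += 2


def brute_force_oracle(
    records: Sequence[DiaryRecord],
    n_days: int = DEFAULT_AVAILABLE_DAYS,
) -> list[ExacerbationEvent]:
    """Reference detector by exhaustive candidate enumeration.

    Semantically identical to :func:`detect_events` but structured
    differently: candidate onsets are enumerated in order, washout
    eligibility is established by searching for any 7-day recorded
    symptom-free run in the inter-event gap, and each event is resolved
    by computing its three possible resolution points (termination pair,
    first record gap, persistence beyond 30 days) and taking the
    earliest.  Intended for small streams; quadratic in the window
    length.
    """
    state, crit, pid = _prepare(records, n_days)
    if pid is None:
        return []
    by_day = {r.study_day: r for r in records}
    events: list[ExacerbationEvent] = []

    barrier = 0  # last day consumed by the previous event's resolution
    need_washout = False
    while True:
        onset = _next_onset(state, crit, n_days, barrier, need_washout)
        if onset is None:
            break
        event, barrier = _resolve_candidate(
            pid, by_day[onset].symptoms, onset, state, n_days
        )
        events.append(event)
        need_washout = True
        if event.censor_reason is CensorReason.WINDOW_END:
            break
    return events


def _next_onset(
    state: list[int], crit: list[bool], n_days: int, barrier: int, need_washout: bool
) -> int | None:
    for d in range(barrier + 1, n_days):
        if crit[d] and crit[d + 1]:
            if not need_washout or _has_free_run(state, barrier + 1, d - 1):
                return d
    return None


def _has_free_run(state: list[int], lo: int, hi: int) -> bool:
    """Any run of WASHOUT_DAYS consecutive recorded free days in [lo, hi]?"""
    for start in range(lo, hi - WASHOUT_DAYS + 2):
        if all(state[i] == _FREE for i in range(start, start + WASHOUT_DAYS)):
            return True
    return False


def _resolve_candidate(
    pid: str,
    onset_symptoms: SymptomSet,
    onset: int,
    state: list[int],
    n_days: int,
) -> tuple[ExacerbationEvent, int]:
    INF = n_days + 10**6

    # earliest termination: minimal worsened day e followed by two
    # recorded symptom-free days; established on day e + 2
    term_e, term_point = None, INF
    for e in range(onset + 1, n_days - 1):
        if state[e] == _WORSE and state[e + 1] == _FREE and state[e + 2] == _FREE:
            term_e, term_point = e, e + 2
            break

    # earliest record gap after the confirmed onset pair
    miss_point = INF
    for m in range(onset + 2, n_days + 1):
        if state[m] == _MISSING:
            miss_point = m
            break

    # earliest worsened day beyond the persistence limit
    persist_point = INF
    for w in range(onset + PERSISTENCE_LIMIT_DAYS + 1, n_days + 1):
        if state[w] == _WORSE:
            persist_point = w
            break

    def make(end, reason, observed_end):
        return ExacerbationEvent(
            patient_id=pid,
            onset_day=onset,
            end_day=end,
            recovery_undetermined=end is None,
            censor_reason=reason,
            onset_symptoms=onset_symptoms,
            observed_end=observed_end,
        )

    if term_point < min(miss_point, persist_point):
        return make(term_e, CensorReason.NONE, term_e), term_e
    if miss_point < persist_point:
        return make(None, CensorReason.MISSING_RECORDS, miss_point - 1), miss_point
    if persist_point < INF:
        return make(None, CensorReason.PERSISTED_OVER_30_DAYS, persist_point), persist_point
    return make(None, CensorReason.WINDOW_END, n_days), n_days


def detect_all(
    records: Iterable[DiaryRecord],
    n_days: int = DEFAULT_AVAILABLE_DAYS,
) -> dict[str, list[ExacerbationEvent]]:
    """Run :func:`detect_events` per patient over a mixed stream."""
    from .records import group_by_patient

    return {
        pid: detect_events(recs, n_days=n_days)
        for pid, recs in sorted(group_by_patient(records).items())
    }
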