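# Methods

This note documents the models, rules and numerical choices behind
`exadiary`, the assumptions they rest on, and what the bundled
synthetic cohort does and does not establish about real data.

## Diary semantics

A diary is one row per patient-day over a fixed 1-based window of 180
available days (hospitalisation days count as available). The central
semantic distinction is **missing day** (no row) versus **recorded
symptom-free day** (a row with all seven flags false): absence of a
record is never evidence of recovery, so missing days cannot serve in
the onset pair, the termination pair, or the washout run, and they
censor any open event. Records may be back-entered up to three days
late (`study_day ≤ entry_day ≤ study_day + 3`); rows outside that
window are dropped and counted at ingestion, and duplicate
(patient, day) rows are resolved by keeping the earliest `entry_day` —
the entry closest to real time, on the view that later entries are
retrospective and less reliable. How a production app backend would
resolve same-day resubmissions is unknowable from the data model, so
the earliest-entry rule is a deliberate artifact decision.

## Detection rules and their edge cases

The criterion (≥1 major of dyspnea / sputum amount / sputum colour,
plus ≥1 further symptom) must hold on **two consecutive recorded
days** to open an event. A worsening "for 2 days" could also be read
as requiring only symptom increase on two days; the stricter
criterion-on-both-days reading follows the validated symptom-diary
definitions this rule descends from, and is what the oracle encodes.

Choices on points the rule set leaves open:

- **Duration is inclusive** (`end − onset + 1`): a minimal event spans
  2 days and has duration 2. "Days after onset that symptoms
  persisted" could also justify `end − onset`; inclusive was chosen so
  the minimal event's duration equals the number of symptomatic days.
- **Continuation uses "any symptom"**, not the full criterion, because
  termination is defined by *symptom-free* days — a single-symptom day
  is not symptom-free, so it prolongs the event.
- **Washout** requires 7 *consecutive recorded* symptom-free days
  between events; the counter resets on any missing or symptomatic
  day, but once achieved, eligibility latches until the next onset.
  The window start counts as eligible for the first event (the cohort
  enters after a stable run-in).
- **Persistence censoring** triggers on a recorded worsened day more
  than 30 days after onset (study-day axis), so the longest complete
  duration is 31 days. Censored events are excluded from duration
  summaries but still classified for reporting/treatment.
- `observed_end` records the last day that informs a censored event
  (day before the first gap; the over-limit worsened day; or day 180)
  and bounds the classification window.

`detect_events` is a single pass; `brute_force_oracle` independently
resolves each candidate onset by computing its three possible
resolution points (earliest termination pair, earliest record gap,
earliest over-limit worsened day) and taking the smallest. Equivalence
of the two on randomized streams, including the 0–60% missingness
range, is the module's primary test.

One property that may look plausible but is **false** is strict
monotonicity under record deletion: deleting the first days of an
episode can shift a later criterion pair into the onset role and so
create a completed event with a new onset. What does hold, and is
tested, is that a degraded-stream completed event sharing its onset
with a full-stream event has the identical end day — deletion can
censor or re-anchor events but never move an established termination.

## Compliance

Overall compliance = 100 × recorded days / available days; duration
compliance = 100 × (last − first + 1) / available days, which is 0
with no records and exactly 100 for a 1–180 span ("days elapsed" could
also be read exclusively; the inclusive span makes the full-window case
exact). Overall ≤ duration always. Discontinuation is reported as the
30-day block (study-time month, not calendar month) containing the last
record. Group comparisons use the Mann-Whitney rank-sum test (exact
enumeration when both groups have n ≤ 8 and the pooled values are
tie-free, otherwise the tie-corrected normal approximation without
continuity correction) or Kruskal-Wallis for >2 groups, two-sided, with
group medians and IQR (P25–P75). No multiple-testing correction is
applied across strata.

## Event classification and CAT impact

Reported = any contact flag (scheduled/unscheduled visit, emergency,
hospitalisation) on a recorded day in `[onset, observed_end]`; treated
= any medication-change flag in the same window. The attribution
window is within-event overlap; flags on non-event days are ignored (a
trailing-days window would be an alternative, but events are defined
purely by symptoms and the data carry no linkage between a contact and
a past episode). When several drug flags occur, the category follows
the precedence antibiotics+corticosteroids > antibiotics >
corticosteroids > bronchodilator increase, mirroring the mutually
exclusive breakdowns used in cohort reports; `other_combination`
remains in the enum for schemas that need it but is unreachable under
this precedence.

Patients partition into no-exacerbation / unreported-only /
reported-only / mixed. CAT change = month-6 − inclusion score;
deterioration ≥2 points is the minimal clinically important
difference. Patients below 60% overall compliance are excluded from
the CAT analysis (their event record is too incomplete to trust the
category), and patients missing a visit score keep their category but
drop out of the group tests (Kruskal-Wallis on CAT change, chi-square
on the MCID proportion).

## Reporting model

Random-intercept logistic regression, events (level 1) in patients
(level 2), fitted by maximising the marginal likelihood with the
intercept integrated out by **adaptive Gauss–Hermite quadrature**:
per patient the integrand is re-centred at its mode (vectorised
penalised Newton) with curvature-matched scaling before the Hermite
rule is applied. Defaults and numerical choices:

- 21 nodes (estimates with 21 vs 51 nodes agree to <1e-4 on fixtures;
  the tests also verify 21-node agreement with fine-grid trapezoid
  integration to better than 1e-6).
- Optimisation over (β, log σ) with L-BFGS-B; log σ is bounded in
  [log 1e-5, log 50], so a true σ = 0 fit lands at the floor and
  reproduces ordinary logistic coefficients.
- Start values from an ordinary logistic fit, which doubles as the
  separation guard: a failed start fit or a runaway coefficient raises
  an explicit separation error instead of returning garbage, and a
  rank-deficient design raises an error naming the collinear columns.
- Wald inference (matching the OR + 95% CI presentation convention);
  continuous predictors enter untransformed so ORs are per unit (per
  day of duration, per onset symptom).
- Univariate screening fits each candidate alone and flags p < .10;
  per-predictor failures are recorded in the screening table, not
  fatal.

The chi-square test is Pearson without continuity correction,
df = (r−1)(k−1), with zero margins rejected.

## Synthetic cohort

The generator emulates the study conditions of a frequent-exacerbator
smartphone-diary cohort: 116 patients × 180 days by default, episode
count per patient Poisson(2.25) truncated to what fits in the window
with ≥9 symptom-free days between episodes, episode duration
2 + NegBin(r=2, p=0.3) (median 6 days, quartiles 4 and 9), per-episode
symptom sets drawn independently per symptom from event-level
prevalences typical of such cohorts (rejection-sampled to satisfy the
detection criterion, and held fixed over the episode so ground-truth
onset and end are unambiguous), and out-of-episode noise days carrying
exactly one symptom with probability 0.02 (so isolated noise can never
meet the two-symptom criterion; adjacent noise days may rarely form
false events, which is intended — it exercises precision scoring).
Reporting follows the same two-level logistic law the model estimates,
with OR 1.15 per day of duration and 1.75 per onset symptom, patient
random-intercept SD 1.0, and intercept −3.15 chosen so the marginal
reported fraction is ≈ 0.38. Treated categories and contact types
follow published conditional breakdowns; reported events get their
contact flag on one uniformly chosen in-episode day. Per-patient
record propensity is Beta(1.2, 0.6) (mean 2/3), applied as
independent day-wise dropout; month-6 CAT is baseline plus a
group-dependent shift (−3 stable, +1 unreported-only, −2
reported-only, +3 mixed) plus integer noise, which makes the CAT stage
testable for sign and ordering only, not magnitudes.

What the generator deliberately does **not** emulate: seasonality and
viral epidemics, within-episode symptom trajectories (fluctuating
symptom sets), monotone abandonment of the diary (dropout here is
day-wise, so duration compliance runs high), back-entry lags,
correlation between symptom inclusions beyond the ≥1-major constraint,
and any dependence of compliance on disease severity. Passing tests
therefore establish the correctness of the *rules and estimators*, not
distributional fidelity to any real cohort.

## Problem sizes and determinism

The bundled checks use 10,000 random 40-day streams for
detector/oracle equivalence, a 200-patient clean cohort for exact
recovery, a 1,000-patient cohort (~2,250 events) for parameter
recovery — where both generating odds ratios are recovered within 2
standard errors — 10,000 events for the degenerate-variance limit, a
5-patient fixture for the integration oracle, and 10,000 null
simulations (n = 50 per group) for nonparametric-test calibration.
All randomness flows from explicit seeds (`numpy.random.SeedSequence`);
the pipeline derives stage seeds from the run seed through a
stage-keyed scheme so stages can be re-run in isolation and identical
config + seed yields byte-identical outputs.

## Known limitations

- Dichotomous symptom flags have floor/ceiling effects: once a symptom
  is "worse than baseline" no further worsening is expressible, and a
  drifting baseline is invisible. The detector inherits this.
- Censored events contribute no duration, so duration summaries are
  conditional on observed recovery and biased short in low-compliance
  patients.
- The reporting model assumes a normally distributed random intercept
  and no random slopes; no multiple imputation for censored durations
  is attempted.
- The 262-event reference table bundled for count checks is a
  synthetic event-level reconstruction of published margins; joint
  structure beyond those margins is assigned deterministically and
  carries no information.
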