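# exadiary

Symptom-diary exacerbation analysis for COPD mHealth cohorts.

Patients with chronic obstructive pulmonary disease (COPD) who keep a
daily smartphone symptom diary generate a longitudinal record from which
exacerbations — sustained worsenings of respiratory symptoms — can be
detected *without* requiring a healthcare contact. This matters because
a large fraction of exacerbations are never reported to a clinician yet
still damage health status. `exadiary` implements the full analysis
chain for such cohorts, for biostatisticians and respiratory-epidemiology
researchers:

1. **Ingestion** of daily diary records (seven dichotomous
   worse-than-baseline symptom flags, medication-change flags,
   healthcare-contact flags), patient baseline tables, and visit-level
   CAT scores, all as delimited text.
2. **Detection** of symptom-defined exacerbation events with explicit
   censoring rules.
3. **Compliance** metrics (overall and duration compliance) and their
   nonparametric comparison across baseline strata.
4. **Classification** of events as reported/unreported and
   treated/untreated, four-group patient categorisation, and CAT-change
   impact with the ≥2-point minimal clinically important difference.
5. **Reporting model**: a two-level (events-in-patients)
   random-intercept logistic regression for the probability that an
   event is reported.
6. A **synthetic-cohort generator** with full ground truth, so every
   stage is testable without access to raw patient data.

## The detection rule

The seven symptoms split into majors (dyspnea, sputum amount, sputum
colour) and minors (cough, wheeze, sore throat, cold). A *criterion
day* has ≥1 major symptom and ≥2 symptoms in total. Then, per patient
over a 180-day window:

- **Onset** = first day of the earliest pair of consecutive *recorded*
  criterion days, after an eligible washout (window start, or ≥7
  consecutive recorded symptom-free days after the previous event).
- The event continues across any recorded day with ≥1 worsened symptom.
- **End** = last recorded worsened day followed by 2 consecutive
  recorded symptom-free days; duration is inclusive (minimum 2 days).
- **Censoring** (`recovery_undetermined`): a missing day before
  termination is established (`missing_records`), worsened symptoms
  recorded more than 30 days after onset (`persisted_over_30_days`), or
  the window closing first (`window_end`). A missing day is *never*
  treated as symptom-free.

The detector is a linear scan; an independent brute-force enumeration
oracle (`brute_force_oracle`) implements the same contract and the two
are required to agree on randomized streams — this equivalence is the
package's primary correctness property.

## The reporting model

For event *j* of patient *i* with covariates $x_{ij}$ (event duration in
days, onset symptom count, baseline characteristics):

$$\mathrm{logit}\, P(y_{ij}=1 \mid u_i) = x_{ij}^\top \beta + u_i,
\qquad u_i \sim N(0, \sigma^2)$$

The marginal likelihood integrates each patient's random intercept out
by adaptive Gauss–Hermite quadrature (21 nodes by default); Wald 95%
CIs come from the inverse observed information and odds ratios are
$e^\beta$. Univariate screening fits each candidate predictor alone and
selects at p &lt; .10 for the multivariable model.

## Worked example

```python
import pandas as pd
import exadiary as ed

cfg = ed.SyntheticCohortConfig(n_patients=116, seed=1)   # 116 x 180 days
cohort = ed.generate_cohort(cfg)

comp = ed.summarize_cohort(cohort.records, list(cohort.baseline.index))
print(round(comp["overall_compliance"].median(), 1))      # 71.4

events = ed.detect_all(cohort.records)
flat = [e for evs in events.values() for e in evs]
print(len(flat), sum(e.recovery_undetermined for e in flat))  # 152 80

cls = ed.classify_events(flat, cohort.records)
tab = ed.tabulate_events(cls)
print(f"{tab.share(reported=False):.1f}%")                # 64.5%

complete = [c for c in cls if not c.event.recovery_undetermined]
fit = ed.fit_random_intercept_logistic(
    [int(c.reported) for c in complete],
    pd.DataFrame({
        "duration_days": [c.event.duration_days for c in complete],
        "onset_symptom_count": [c.event.onset_symptom_count for c in complete],
    }),
    [c.event.patient_id for c in complete],
)
print(fit.odds_ratios.round(2).to_dict())
# {'intercept': 0.01, 'duration_days': 1.39, 'onset_symptom_count': 1.68}
```

Reading the output: with realistic (~67%) diary compliance, 152 of the
injected episodes are detectable, and 80 of those are censored because a
missing day interrupts the stream before recovery can be confirmed —
exactly the behaviour expected of real cohorts, where missing data and
censoring dominate. 64.5% of detected events involved no healthcare
contact (unreported). The two-level fit on the 72 complete events
estimates the odds of reporting rising by 39% per extra day of duration
and 68% per extra onset symptom; at this small event count the
estimates are noisy — the parameter-recovery test below uses a
1,000-patient cohort, where both recover their generating values.

The same pipeline runs from the shell:

```bash
exadiary simulate --out sim --seed 1
exadiary detect --diary sim/diary.csv --out events.csv
exadiary run --config run.yaml      # full pipeline with manifest
```

Output column orders are stable: diary files as
`patient_id,study_day,entry_day,<7 symptom flags>,<3 medication
flags>,<4 contact flags>`; event files as
`patient_id,onset_day,end_day,duration_days,recovery_undetermined,censor_reason,observed_end,onset_symptom_count,severity_bin,<7 onset symptom flags>`.

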