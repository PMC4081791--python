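# eddx

Item-level operationalization of DSM-5 and DSM-IV eating-disorder
diagnoses, a synthetic clinical cohort simulator with recoverable ground
truth, and the group-comparison statistical battery used in naturalistic
eating-disorder cohort studies.

## Who this is for

Researchers studying the boundaries of the DSM-5 eating-disorder
nosology — in particular the residual OSFED categories (atypical anorexia
nervosa, purging disorder, sub-threshold bulimia/binge-eating disorder)
and the unspecified remainder (UFED) — who need a deterministic, auditable
rule engine for assigning diagnoses from interview and questionnaire
items, plus a way to test an entire analysis pipeline without access to
clinical data.

## What it implements

**Diagnostic engine** (`eddx.engine`). Rules consume a `PatientRecord`
holding interview indicators (boolean "regular behavior" flags at the
interview's twice-weekly/3-month threshold, cognitive criteria,
amenorrhea), 28-day questionnaire behavior counts, BMI, scale scores, and
Axis-I comorbidity flags. The lower once-weekly DSM-5 frequency criteria
are met by the interview flag or, as a provenance-tracked fallback, by a
28-day count ≥ 4. Category predicates:

- **AN** (RAN/ANBP): BMI < 18.5, fear of weight gain (or persistent
  weight-gain-preventing behavior), and a disturbed-experience criterion;
  binge/purge subtype when regular binges or purging are present.
- **BN**: weekly objective binges + weekly compensation + overvaluation
  of weight/shape, AN excluded.
- **BED**: weekly objective binges + marked distress + no weekly
  compensation.
- **PD**: regular purging (interview-established), BMI > 18.5,
  overvaluation or weight phobia, no regular objective binges.
- **AAN**: the AN cognitive picture with regular restrictive/compensatory
  behavior at BMI ≥ 18.5 (a surrogate for unobservable "significant
  weight loss"); overlaps PD by construction and is resolved purely by
  category precedence (`--precedence`).
- **SubBN/SubBED**: the BN/BED pattern below the weekly threshold.
- **UFED**: the minimal residual rule — ≥ 1 psychological symptom plus
  ≥ 1 behavioral or physical symptom.

Remission at 12 months = meets neither any DSM-IV rule nor the minimal
residual rule.

**Synthetic cohort** (`eddx.cohort`). Latent labels are drawn from a
configurable mixture; each label's records are generated from a
criteria-forced prototype plus truncated-normal scale scores, Bernoulli
behavior presence with truncated-Poisson 28-day counts, Bernoulli
comorbidity, and noise flips restricted to non-defining indicators — so
with `noise=0` the engine recovers the latent label exactly. A
row-stochastic transition matrix (including a remission column) drives
12-month follow-up generation with configurable retention. All defaults
are calibrated to published summary tables of a 2233-patient specialist
care cohort.

**Statistics** (`eddx.stats`). Cap-then-gap-delete outlier rule;
classical and Welch ANOVA with partial η²; Scheffé and Games–Howell
pairwise contrasts under the dual significance gate (p < 0.01 **and**
|Cohen's d| ≥ 0.50); Pearson χ² (no continuity correction) with
standardized residuals and Fisher fallback; φ/Cramér's V with the
Rea–Parker magnitude taxonomy; residual gain scores; Cronbach's α.

**Longitudinal outcomes** (`eddx.longitudinal`). Cross-over/stability
tables, per-label and overall remission rates, migration summaries with
configurable excluded destinations, and residual-category composition
arithmetic.

## Worked example

```sh
eddx report --seed 1 --out demo_reports
```

generates the default 2233-patient cohort, diagnoses it under the default
precedence (PD tried before AAN), runs the statistical battery, and
prints the summary metrics, ending with:

```
  "n_baseline": 2233,
  "overall_remission_percent": 39.0,
  "pd_aan_subbed_osfed_share_percent": 89.0,
  "pd_cohort_share_percent": 8.3,
  "pd_osfed_share_percent": 33.0,
  ...
```

i.e. in this synthetic draw purging disorder is 8.3% of the cohort and
33% of the residual (OSFED + UFED) group, and 39% of followed patients
are in remission at 12 months. The bundle written to `demo_reports/`
contains the cohort CSV with its JSON truth sidecar, distribution /
scores / behaviors / comorbidity / cross-over tables, the outlier log,
and `metrics.json`; identical seed and config reproduce the bundle
byte-for-byte. `eddx generate` and `eddx diagnose --precedence ...` expose
the individual stages; swapping PD and AAN in the precedence shows the
characteristic collapse of the PD group into AAN.

## Layout

```
src/eddx/
  records.py       patient record model
  engine.py        DSM-IV / DSM-5 rule engine, remission, precedence
  cohort.py        synthetic cohort generator + ground truth
  calibration.py   published summary tables as generative parameters
  stats.py         omnibus/post-hoc/categorical/reliability battery
  longitudinal.py  cross-over, remission, migration, composition
  pipeline.py      end-to-end report bundles
  cli.py           eddx generate | diagnose | analyze | report |
                   reproduce-targets
```

See `docs/methods.md` for modelling assumptions, parameter choices, and
known limitations.
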