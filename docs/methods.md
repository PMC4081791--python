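# Methods

## The diagnostic model

The engine operationalizes eating-disorder diagnoses from two item
sources with different measurement properties: a structured clinical
interview whose behavior items are thresholded at the DSM-IV level (at
least twice weekly for three months, the `regular_*` flags), and a
self-report questionnaire that records 28-day episode counts. DSM-5
lowered several frequency criteria to once weekly; because the interview
cannot distinguish once-weekly from absent, the engine meets a weekly
criterion either from the interview flag or — recorded as
`edeq_fallback` in the criteria profile — from a 28-day count of at
least 4 (four weeks × once weekly). The fallback is deliberately
asymmetric: it can only *add* information where the interview is silent,
and the two purging-disorder conditions (regular purging present, regular
objective binges absent) are interview-only, so questionnaire counts can
neither create nor destroy a PD assignment. This mirrors clinical
reality, where questionnaire-reported binges are common in groups whose
diagnosis nominally excludes them.

"Significantly low weight" is BMI < 18.5 everywhere, the same cut that
gates PD from above; atypical AN's "significant weight loss" criterion
is unobservable at the item level, so AAN is operationalized as the full
AN cognitive picture plus at least one regular restrictive/compensatory
behavior at BMI ≥ 18.5. That makes the PD/AAN overlap structural: a
normal-weight purger with weight phobia satisfies both patterns, and
only the category precedence decides. The default precedence tries PD
before AAN — the ordering that maximizes the PD group, preferred because
the PD definition is complete while the AAN surrogate is not. Every
category predicate depends on the record alone, never on the position of
other categories, so permuting the precedence redistributes records among
overlapping categories but cannot change whether a record is diagnosed at
all; this invariant is property-tested.

DSM-IV assignment exists for two purposes: the remission rule and the
historical interview thresholds. Its residual (EDNOS) is the minimal
symptom rule (≥ 1 of four psychological symptoms plus ≥ 1 behavioral or
physical symptom) *or* the binge-eating presentation (regular binges with
distress, no compensation) — the latter because binge-eating disorder was
itself a canonical DSM-IV EDNOS example and carries no cognitive
criterion, and without it a BED-pattern follow-up would be counted
remitted. Remission at 12 months = DSM-IV NONE and the minimal rule not
met.

One stated invariant was narrowed during design: "adding a symptom never
moves a formal diagnosis to NONE" cannot hold for a pure binge-eating
presentation with no cognitive symptom (gaining compensation removes BED,
and no residual rule catches a record without a psychological criterion).
The property is therefore asserted — and is provable — for records
carrying at least one of the four psychological flags, for which a lost
formal diagnosis lands at worst in the unspecified residual.

## The synthetic cohort

The generator's role is to provide item-level data with the statistical
structure the analysis assumes, plus usable ground truth. Per latent
label it draws:

- **BMI and age**: truncated normal at the published per-group means/SDs,
  with truncation bounds that keep each label's anthropometric gate
  satisfied (AN subtypes below 18.4; normal-weight diagnoses above 18.6).
- **Scale scores** (EDE-Q global, impairment 0–48, psychiatric distress
  0–3, three self-image dimensions): truncated normal at the published
  per-group means/SDs; instrument ranges enforced by truncation. The four
  EDE-Q subscales are drawn around the global score (SD 0.5) since no
  per-group subscale table is published.
- **Behaviors**: presence is Bernoulli at the published per-group
  prevalence of reporting ≥ 1 episode/28 days; counts among reporters are
  Poisson at the published per-group mean, right-truncated at a 56-episode
  cap (two per day). The 0–6 ordinal fasting item is drawn analogously.
- **Comorbidity**: Bernoulli at the published per-group Axis-I rates.
- **Interview flags**: defining-true flags on, defining-false flags off,
  and *only the remaining free flags* flipped with probability `noise`
  (default 0.05, a plausible item-level inconsistency rate). Confining
  noise to non-defining indicators is what keeps the latent label exactly
  recoverable at `noise=0`.

Two generation-time constraints go beyond the published tables. First,
counts for behaviors whose *regularity* a label's rule forbids (objective
binges for PD, compensation for BED and sub-BED, both for sub-BN) are
drawn in [1, 3] — present but below the weekly fallback threshold.
Without this the questionnaire fallback would re-label, e.g., a PD record
with self-reported binges as BN, and ground truth would be unrecoverable
even noise-free; with it, the generator reproduces the published pattern
of PD patients reporting occasional binges while remaining PD. Second,
groups without published parameter rows reuse the nearest published ones
(sub-BED ← BED, sub-BN ← BN), and single-case or missing frequency cells
are filled with a small mean of 2.0.

Follow-up generation draws each patient's 12-month target from the
row-stochastic transition matrix (rows calibrated from the published
530-patient cross-over counts, row count / row total). Remission targets
get records with no interview symptoms, zero counts, BMI drawn in the
normal range, and low residual scale scores, so they fail both rule sets
outright; diagnosis targets are regenerated from that label's model.
Attrition is missing-completely-at-random at `1 - retention` (default
retention 1.0; the study's own follow-up completeness was ~50%, but the
emulation is a rate, not a mechanism).

Within-group correlations among scales are not modelled (scales are
independent given the label); the published tables contain no
correlation structure to calibrate against, and the flag is documented
here rather than silently implied. Consequently the generator supports
distribution-level and rule-level claims (recovery, mixtures,
transitions, test calibration) but not claims about multivariate
dependence in real data.

## Statistical protocol

- **Outliers**: values above a pre-defined per-variable plausible maximum
  are truncated to it; then, within each diagnostic group, the top
  distinct value (with ties) is deleted whenever its z-score (sample SD,
  n−1) exceeds the next-highest distinct value's by more than 1,
  recomputing after each deletion. Groups smaller than 3 are capped but
  exempt from deletion (SD too unstable), with a warning.
- **Omnibus**: classical one-way ANOVA with partial η² =
  SS_between/(SS_between+SS_within); Welch's F with Welch–Satterthwaite
  denominator df when heteroscedasticity (Levene, p < 0.05) coincides
  with a small group (min n < 30) — the trigger is codified this way
  because "unequal and small groups with unequal variances" needs an
  operational rule; an override flag exists.
- **Pairwise contrasts**: Scheffé after a classical omnibus (pairwise F
  scaled by the omnibus numerator df — provably never more significant
  than the unadjusted pairwise test), Games–Howell after Welch
  (studentized-range with per-pair Welch df; verified against an
  independent reference implementation to 1e-6). A contrast is reported
  only when p < 0.01 *and* |pooled-SD Cohen's d| ≥ 0.50. The dual gate's
  familywise false-report rate under a 7-group global null at the
  calibration group sizes is measured by simulation (1000 replicates in
  the test suite, 500 in the acceptance script — sizes chosen to keep the
  runs brief while leaving the binomial error on the rate small relative
  to the 1% criterion).
- **Categorical**: Pearson χ² without continuity correction (the
  convention matching the published values exactly), standardized
  residuals (O−E)/√E, pairwise 2×2 post hocs at α = 0.001 with Fisher's
  exact test when any expected cell < 5, φ = √(χ²/N), and the Rea–Parker
  magnitude bins applied half-open exactly as printed.
- **Change**: residual gain scores are residuals of the follow-up-on-
  baseline regression fitted on the pooled sample (pooling preserves
  between-group differences in change; per-group fitting would absorb
  them).
- **Rounding**: percentages round half-up for display; machine outputs
  keep raw proportions. Cohen's d is pooled-SD (not bias-corrected):
  the conventional default where no correction is specified.

## Longitudinal arithmetic

The cross-over table counts intake label × follow-up outcome (follow-up
label, or remission). Migration excludes the remission column and the
diagonal; the headline "mean migration" is the *unweighted* mean of row
percentages — the patient-weighted pool does not reproduce the published
14% — with the two absorbing residual destinations (UFED, AAN) excluded
by default. The residual-umbrella composition uses a denominator
including UFED (AAN + sub-BN + sub-BED + PD + UFED = 576 at the
calibration counts), which is the only reading that reproduces the
published 32%/88% shares. The published "average 39% (range 17–55%)"
for migration including UFED/AAN computes to ≈ 40% from the table counts;
the per-row values (e.g. 55% and 17%) are asserted, the mean is reported
unrounded and left as a noted discrepancy.

## Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng` seeded from the
  config; identical config + seed yields byte-identical cohorts and
  report bundles (CSV floats written as `%.17g`, read back with
  round-trip parsing).
- Zero-variance degenerate cases: identical groups give F = 0/p = 1 and
  d = 0; Welch ANOVA refuses all-zero variances; Cohen's d, Cronbach's α,
  and residual gains raise on zero denominators rather than returning
  NaN.
- Missing interview items are treated upstream as absent (conservative
  and auditable); the engine itself is total on valid records.
- Problem sizes used by the checks: the truth-table comparison covers all
  3 × 2¹⁴ = 49 152 flag/BMI combinations; generator recovery uses
  n = 5000 with 3-binomial-SE bands; the cohort demo uses the full
  calibration size n = 2233.

## Known limitations

- The interview item dictionary is a reconstruction; the instrument's
  exact item set is unpublished.
- Whether sub-threshold BN requires the full 3-month duration at
  sub-weekly frequency is unspecified; the engine requires presence, not
  duration (configurable in the sense that the predicate is a single
  function).
- Published per-group scale means/SDs are treated as exact generative
  parameters; sampling error in those tables propagates into the
  synthetic cohort.
- Scales are conditionally independent given the label (see above), and
  the transition matrix is first-order (no duration-of-illness effects).
- The anxiety-comorbidity row of the published counts is internally
  inconsistent (cells sum to 356, printed total 365); it is carried for
  generation but not asserted in any reproduction check.
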