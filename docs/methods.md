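# Methods

## Instruments and decoding

The survey codebook ships as a machine-readable JSON dictionary
(`steppedcare/data/survey_dictionary.json`) with one entry per variable:
allowed codes, the prefer-not-to-answer code (999 → missing), yes/no
coding (raw 1 = Yes, 2 = No; decoded 1/0), and the term-dependent cannabis
dialect (terms 1–2: weekly 0–4 scale, screen at ≥ 2; later terms: monthly
0–5 scale, screen at ≥ 3).  Decoding is idempotent and rejects any
out-of-scale code, naming the variable and rows.

Instrument totals are plain item sums: PHQ-9 (9 items, 0–27), GAD-7
(7 items, 0–21), and their abbreviated forms PHQ-2/GAD-2 (first two items,
0–6).  A total of 10+ on the full forms is the conventional positive
screen; the abbreviated forms screen at ≥ 3 and are used only for
reporting, never inside the rules.

Severity bands are defined by configurable edges, defaults:

| band        | PHQ-9 | GAD-7 |
|-------------|-------|-------|
| moderate    | 10–14 | 10–14 |
| severe      | 15–19 | 15–18 |
| very severe | 20–27 | 19–21 |

The combined band is the more severe of the two.  Functional impairment is
either follow-on difficulty item (DIFF) at ≥ 2 ("Very difficult");
structurally absent DIFF values count as not impaired — the rules
otherwise run on the imputed, complete dataset.  The PSS-4 stress clause
flags when any item reaches its most-stressed end: Q1 ≥ 3 or Q4 ≥ 3
(negatively worded) or Q2 ≤ 1 or Q3 ≤ 1 (positively worded).  Substance
screening is per-variable and scale-aware (weekly-scale drugs at ≥ 2,
monthly-scale drugs at ≥ 3, binge drinking at weekly or more, i.e. ≥ 3);
where a prose shorthand ("score ≥ 2 for any drug") conflicts with the
per-variable thresholds, the per-variable table governs.

## Rules engine

Level 1 (urgency): lifetime suicide attempt or self-harm is crossed with
current suicidal thoughts (PHQ-9 item 9 ≥ 1).  Both positive → urgent
in-person assessment.  Exactly one positive → urgent only with severe
debilitating depression (default PHQ-9 ≥ 20 with impairment) or any
substance use.  Lifetime ideation items (wish-dead, suicidal ideation) are
excluded by default; a config switch adds them to the lifetime screen.
PSS-4 does not participate in level 1.

Levels 2a/2b/2c map (severity band, impairment-or-stress flag) to a care
range through configurable tables.  The defaults were reconstructed so
that, routed through them, the per-cell cohort counts of the published
validation decompose its per-recommendation and per-band totals exactly —
this consistency is enforced as arithmetic identities in the test suite.
2b (lifetime diagnosis history: anxiety, mood, psychotic, eating, or
neurodevelopmental) and 2c (substance use) add a self-guided layer: history
or use alone, with no symptom band, maps to self-guided support.  2c
escalates the very-severe cells toward community addiction services.

Combination keeps the recommendation with the highest high level; ties
break by the higher low level, then by source (2a > 2b > 2c > ML).  The
integrated engine evaluates level 1, then 2a; only students passing both
are screened in parallel by 2b, 2c and the risk models, whose positive
prediction contributes a self-guided recommendation.  A config flag
(`evaluate_l2bc_on_all`) instead runs 2b/2c on everyone past level 1, for
cohort accounting that uses the full non-urgent denominator.

## Imputation

Chained equations with, per variable, predictive mean matching (ordinal
and numeric) or a multinomial-regression draw (unordered categoricals such
as academic program).  Defaults: m = 10 datasets, 10 iterations, k = 5
donors — m is as used in the source workflow; the iteration count and
donor count follow common chained-equations practice and are configurable.
The visit sequence is ascending missingness fraction; initial fill draws
from observed marginals.  PMM fits an ordinary least-squares prediction
from all other variables and draws uniformly among the k observed values
with closest predictions, so imputations always lie in the observed
support.  Instrument totals are never imputed; they are recomputed from
items in every completed dataset (passive imputation).  The m datasets are
consolidated to a single analysis dataset by the per-cell mode over the
originally missing cells, ties broken toward the smallest code, totals
recomputed afterwards.  Follow-up outcome items are never imputed — a
fabricated outcome would leak into the model labels.  No Rubin pooling is
performed; the deliberate design is a single consolidated dataset.

## Risk models

Eligibility: not urgent under level 1, not fired by 2a, follow-up data
present.  Features are the a-priori baseline set — symptom items (all, or
only the first two of each questionnaire in the abbreviated variants),
both DIFF items, the twenty yes/no history/family/adversity/suicidality
variables (0/1), and the four PSS-4 items.  Labels are time-2 totals ≥ 10
for the variant's outcome; no time-2 information enters the features.

Training: 70:30 stratified split; XGBoost with fixed shallow settings
(150 trees, depth 3, learning rate 0.1, single thread) — only
`scale_pos_weight` is grid-searched over {1, negatives/positives} by mean
macro F1 across stratified 10-fold cross-validation (macro F1 weights both
classes equally under the ~1:3.7 imbalance).  The winner is refit on the
full training set.  The decision threshold is then tuned on the winning
setting's pooled out-of-fold predictions: the largest threshold whose
out-of-fold sensitivity meets the target (default 0.93), i.e. maximal
specificity subject to the sensitivity constraint; ties at the threshold
classify positive.  The threshold is fixed before any test-set contact.
The 0.93 default targets a comfortable margin over a 90% sensitivity
floor; with ~140 test positives at n = 2285 the held-out sensitivity still
carries a standard error near 0.02, so individual seeds can land a few
points either side of the target — the package reports medians across
seeds for this reason.

## Metrics

From the confusion matrix at a threshold (positive iff score ≥ threshold):
accuracy, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN), F1 of the positive class, and macro F1
(unweighted mean of per-class F1, the negative class using NPV and
specificity).  Ratios with zero denominators are reported absent, never
zero.  Threshold curves tabulate these over all observed score cutoffs.

## Explainability

Attributions are exact tree-path Shapley values computed natively by
XGBoost on the margin (log-odds) scale, where additivity is exact: per
student, contributions plus the base value equal the margin prediction
(checked to 1e-6 relative to the prediction magnitude; attributions are
stored in single precision).  Reported importance is the mean absolute
contribution over all evaluated predictions, computed on the test
partition.  Because the generator drives all items of an instrument from
one latent severity, individual item importances are intrinsically
near-tied; for questions about *what* the model learned (e.g. whether the
strongest planted effect is recovered) the package pools item
attributions into their instrument-total terms (`grouped_ranking`), which
is exact under additivity and gives well-separated, seed-stable ranks.

## Synthetic cohort generator

The generator is a test harness with known ground truth, not a clinically
validated population simulator.  Ordinal items arise from one standard
normal latent per instrument (depression and anxiety latents correlated
0.6, stress latent loading on both) with loading 0.75 and equally spaced
thresholds per scale; thresholds were calibrated once so the full-cohort
totals approximate published entry-survey descriptives (PHQ-9 mean ≈ 7.7,
SD ≈ 6; GAD-7 mean ≈ 8, SD ≈ 5.3).  Items within an instrument are
exchangeable except the two rare PHQ-9 items (psychomotor change,
suicidal thoughts), which carry positive threshold offsets.  Yes/no
variables are independent Bernoulli draws in raw 1/2 coding (lifetime
anxiety 0.15, mood 0.10, family mood 0.20, bullying 0.25, others
0.02–0.30); substance items are categorical draws on their native scales
with a deliberately heavy binge-drinking distribution (P(weekly+) = 0.20).
These rates make roughly a fifth to a quarter of a default cohort trigger
the level 1 workflow and leave every downstream stage non-empty.

Follow-up status per outcome is Bernoulli with probability
expit(b0 + 0.15·PHQ9 + 0.10·GAD7 + 0.5·anxiety history + 0.4·family mood
+ 0.4·bullying + 0.2·PSS-4 item 4), the intercept solved numerically so
the realized prevalence matches its target (default 0.21 per outcome,
the ~1:3.7 imbalance).  Given status, time-2 items are constructed to
total ≥ 10 (positive) or < 10 (negative).  Missingness is injected MCAR
or MAR (rates raised for male and older-band students to exercise
chained-equations conditioning on auxiliaries); outcome columns and the
MAR auxiliaries are never blanked, and the truth mask is returned.

What passing tests do and do not show: the generator plants a smooth
logistic signal on independent history variables and latent-driven items,
so it demonstrates that the pipeline recovers planted structure, hits
calibrated prevalences, and satisfies its contracts — it does not
demonstrate performance on real students, where history and symptoms
correlate, items have idiosyncratic endorsement profiles, and missingness
need not follow the modelled mechanisms.

## Numerical and design choices

- Reported experiment sizes: the tuning experiment uses cohorts of
  n = 2285 with 10 seeds; the null-signal check uses n = 5000 (chance-level
  AUC band 0.45–0.55); rank-stability uses n = 6000 where grouped
  importances separate cleanly.
- Determinism: every stochastic step takes a seed; generator streams are
  derived from (seed, stage) pairs; XGBoost runs single-threaded with the
  histogram method, so identical configs reproduce outputs byte-for-byte
  on one platform (floating-point reproducibility across platforms is not
  guaranteed).
- Degenerate inputs: single-class CV folds trigger a reshuffle with a
  warning; PMM reduces k with a warning when donors are scarce; fully
  missing columns, empty eligible cohorts, and classes with fewer than two
  members raise informative errors.
- The pipeline's run manifest records the config, its hash, seeds, package
  version and per-stage counts, sufficient to reproduce a run.

## Known limitations

- Rule mapping tables are reconstructions consistent with published
  aggregate counts, not a transcription of the original decision trees;
  they are config-overridable.
- The generator omits history–symptom correlation and survey-wave effects;
  binary variables do not shift the symptom latents.
- Threshold tuning assumes out-of-fold scores are exchangeable with
  final-model test scores; no recalibration is applied.
- No reliability/calibration analysis of predicted probabilities is
  provided; reported metrics are discrimination-style only.
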