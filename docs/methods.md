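# Methods

This note documents the models and procedures `drsf` implements, the
assumptions behind the synthetic claims generator, and the numerical and
design choices that were genuinely open.

## The survival forest

Trees are grown on bootstrap samples drawn with replacement (the out-of-bag
remainder is kept per tree). At each node `mtry` features are drawn without
replacement and up to `nsplit` random candidate cut points per feature are
scored by the standardized two-sample log-rank statistic

    Z = |sum_j (d1j - dj * n1j/nj)| / sqrt(sum_j dj (n1j/nj)(1 - n1j/nj)(nj - dj)/(nj - 1))

over the pooled distinct event times of the node, with the hypergeometric
variance. A split is admissible when both children keep at least
`min_samples_leaf` bootstrap members and Z > 0; otherwise the node becomes a
leaf storing the Nelson–Aalen cumulative hazard of its in-bag members.
Event/censoring ties at the same time keep the censored subject in the risk
set at that time (events first). The random cut-point search (default
`n_splits = 10`) bounds the per-node cost the way the reference RSF
implementations do; drawing candidates from the node's observed values makes
an exhaustive search available in the limit of large `n_splits` for oracle
comparisons.

Defaults: 500 trees, `mtry = ceil(sqrt(p))`, `min_samples_leaf = 15`.
The tree count is the one parameter the method fixes (tree-vote fractions
are quoted out of 500 trees); the others follow common survival-forest
practice and are exposed as estimator parameters. Missing feature values are
rejected rather than imputed — the generator produces complete data, and
silent imputation would change the method under test.

Predictions: the forest cumulative hazard for a subject is the pointwise
tree average of the terminal Nelson–Aalen curves, evaluated on the grid of
distinct training event times (a superset of every leaf's event times, so
the step functions are unchanged by the common grid). The ranking marker is
the ensemble mortality, the sum of H over that grid — a monotone functional
of the predicted hazard.

Variable importance is Breiman–Cutler permutation importance on OOB data:
the OOB ensemble mortality is recomputed with one feature's values permuted
within each tree's OOB sample, and the importance is the increase in OOB
error, where error = 1 − Harrell's C. Split frequency (fraction of trees
using the feature at least once) is reported alongside, and is the
"tree-vote" measure used for local/global importance across windows.

Two-step selection: features with negative permutation importance are
dropped; survivors are ranked by importance and nested forests on the
top-2, top-3, ... prefixes are fitted until the OOB concordance gain drops
below `delta` (default 0.005 — the stopping threshold for "little or no
incremental effect" is not pinned by the method and is exposed as a
parameter). If every feature has negative importance the single top-ranked
feature is kept, with a warning.

## The dynamic layer

A window model is trained at index date T on the cohort identified there
(67/33 train/validation split) and deployed at T + 180 days, where features
are re-extracted for the test cohort. For a target prediction window, the
ensemble of the N most recent window models averages *daily hazard
increments*: each member's predicted cumulative hazard is evaluated on whole
days relative to its own prediction index, differenced, aligned on the
target window's daily grid, and averaged over the members whose 180-day
prediction interval covers the calendar day and whose cohort contains the
subject (N counts only available windows; a subject present in no member
window gets an explicit no-prediction error). The survival curve accumulates
the averaged increments: S(t) = exp(−Σ_{u≤t} h̄(u)).

Choices made where the design was open:

* **Grid.** Members' hazards are aligned on a daily grid relative to the
  target index date; the method frames risk "in a day unit" and daily
  resolution loses nothing relative to the event-time grids.
* **Weights.** The combination is the unweighted mean over available
  windows; recency enters only through window eligibility. An optional
  per-member weight vector is exposed for recency weighting, but the
  unweighted mean is the default and the documented behavior.
* **Reduction.** With one member the ensemble arithmetic (sum of one
  increment matrix, divided by a count of one, cumulated in the same order)
  is bitwise identical to the plain forest pipeline's daily predictions;
  the acceptance suite asserts exact equality.
* **Evaluation marker.** For a window ensemble at a fixed horizon the
  marker is the cumulative ensembled hazard at that horizon — the monotone
  transform of S(t) consistent with ensemble mortality for a single forest.

## Cohort and features

Cohort inclusion requires a claim line whose diagnosis codes intersect the
14-code CHF set (Quan/Elixhauser ICD-9 enumeration, matched as exact
normalized strings — the set enumerates children of 428 explicitly) in the
half-open window [index − 12 months, index). Evidence is accepted from any
care setting and any diagnosis position; the outcome requires the
*principal* diagnosis of an inpatient line to be a CHF code.

The outcome scan keeps the first admission in (index, index + 180 days];
an admission starting within 30 days of the discharge of the previous kept
admission is dropped as a readmission, and a dropped readmission does not
reset the discharge anchor. The chain is evaluated over in-window candidates
only — an admission shortly after a pre-index discharge is treated as a new
admission, a reading the outcome definition leaves open. An admission on the
index date itself is prevalent, not incident, and is excluded with a
warning; day counting is 1-based whole days.

All feature windows are half-open [index − L, index), so claims dated on or
after the index date can never influence a feature (the leakage test
appends future claims and asserts an unchanged matrix). Categorical fields
are one-hot encoded with an explicit `NA` level. The Charlson index uses the
Quan (2005) ICD-9 prefix mapping with the standard weights and the
diabetes/liver/malignancy hierarchies. The chronic-condition and
exacerbation code sets are configurable, with small illustrative defaults —
stand-ins for the longer condition lists a production feed would supply.
"Most recent care location" maps ED lines to Outpatient and breaks same-day
ties by acuity (Inpatient > SNF > HHA > Outpatient); no qualifying line in
the trailing month means "home".

## The synthetic claims generator

The generator emulates the statistical structure of a monthly claim feed
for an elderly CHF sub-cohort:

* **Roster**: ages uniform on [60, 99) at simulation start; sex, race and
  Medicare/dual status codes drawn with frequencies matching a published
  descriptive table for such a cohort.
* **Ground truth**: chronic-condition indicators (Bernoulli, default
  prevalences again matching that table) plus three continuous N(0, 1)
  utilization-severity scores that scale the ED/outpatient/prescription
  claim intensities via exp(γz − γ²/2) (mean-corrected so the configured
  monthly intensity is exact; γ = 0.7).
* **Claims**: background lines arrive as Poisson streams split across
  settings; scheduled evidence lines stamp each flagged condition's ICD-9
  codes (CHF roughly quarterly, so every trailing 12-month window contains
  evidence; other conditions roughly yearly, covering the 36-month
  lookback).
* **Admissions**: a homogeneous Poisson process per beneficiary with rate
  λᵢ = λ₀ exp(βᵀxᵢ). The process is memoryless, so the time to first
  admission from *any* index date is Exp(λᵢ) — the stream is stationary
  across sliding windows, which is what makes multi-window comparisons
  well-posed. λ₀ is calibrated so the null 180-day event probability equals
  `target_event_rate_6mo` (default 0.05). Censoring is administrative only
  (end of the 180-day window). Admissions materialize as inpatient lines
  with a CHF principal diagnosis and a short length of stay.

Default scale: 5,000 beneficiaries over Feb 2011 – Sep 2015 (36 months of
lookback before the first risk month), ~5% six-month event rate, default
hazard on renal failure, pulmonary circulation disorders and chronic
pulmonary disease (log hazard ratios 0.5 / 0.7 / 0.4). Two presets define
the study conditions used throughout the tests: `null_config` (every β = 0)
and `strong_signal_config` (three severity scores with |β| = 1 among p = 10
candidate features, raised claim intensity so the scores are recoverable
from window claim counts). The signal features are continuous by design:
with three Bernoulli(0.5) indicators at |β| = 1 even the *true* risk score
has concordance ≈ 0.69, so no method could demonstrate C > 0.7; with three
N(0, 1) scores the oracle concordance is ≈ 0.79 and a 0.7 bar genuinely
tests the forest.

What the generator does **not** emulate: real CCLF record layouts, coding
noise and miscoding, seasonality and secular drift, enrollment churn,
death and competing risks, recurrent-admission clustering beyond the
Poisson process, and regional/provider effects. Passing tests therefore
show the machinery is correct and well-calibrated under a known
proportional-hazards world — not that the reported discrimination levels
transfer to any particular real feed.

## Evaluation

Harrell's C counts pairs where the strictly shorter time ends in an event;
marker ties score 1/2 (time-tied pairs are not comparable). The
cumulative/dynamic AUC at horizon τ compares cases (event by τ) with
controls (event-free past τ), weighting cases by the inverse Kaplan–Meier
censoring probability 1/G(t−); with no censoring before τ it reduces to the
empirical case/control AUC. Subjects administratively censored exactly at τ
are controls — they are known event-free through the horizon (this is what
makes AUC at the full 180-day horizon well-defined under administrative
censoring; estimators that require controls strictly beyond τ cannot score
that horizon at all). Confidence intervals are percentile bootstrap with
cases and controls resampled separately (counts preserved), 500 replicates
by default, markers held fixed (the model is not refitted per replicate);
replicates with an undefined metric are redrawn with a retry cap.

## Problem sizes and tolerances

The test suite runs every stochastic check at reduced but stated sizes:
oracle equivalence at n ≤ 30 over 100 draws (tolerance 1e-10 against
textbook-formula implementations, with lifelines/scikit-survival as
additional cross-checks); null calibration on 10 streams of 2,000
beneficiaries (across-seed mean concordance in [0.45, 0.55], computed
without the selection step, since OOB concordance after selecting features
on the same split measures selection bias rather than forest calibration);
signal detection on 10 pairs of n = 1,000 ground-truth tables with
100-tree forests; ensemble comparisons on 10 streams of 800 beneficiaries
with five monthly windows; bootstrap coverage over 100 datasets of n = 600
at 200 replicates against a truth estimated once at n = 50,000. The
acceptance script averages three replicate streams per quantity at the same
sizes. Degenerate inputs are defined, not special-cased: zero log-rank
variance scores 0, an all-censored sample has an empty hazard grid,
metrics raise an explicit undefined-metric error when no comparable pairs,
cases or controls exist.

## Known limitations

Recurrent admissions are reduced to the first valid admission per window;
competing risks (death) are not modeled; window size and ensemble width are
fixed rather than tuned; the unweighted window mean ignores possible
recency weighting (exposed as an option); effect sizes are not estimable
from the forest (importance is rank-based); and the Charlson/exacerbation
code lists shipped as defaults are illustrative, not clinical references.
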