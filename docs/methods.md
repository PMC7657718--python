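# Methods

This note records the modelling choices behind the package: what each stage
assumes, which defaults matter and why, what the synthetic cohorts do and
do not emulate, and where the design was genuinely open.

## Data model

A *touchpoint* is one observation `(user_id, timestamp, variable, value,
source)`.  Variables are typed once per log: **numeric** (all values
parse as numbers), **categorical** (none do), or **event** (all values
empty; events carry an implicit value of 1).  A variable mixing numeric and
categorical values is a hard error naming the variable — silently coercing
either way corrupts downstream aggregation.  Rows with unparseable
timestamps are dropped with a logged count rather than aborting a whole
ingest for one bad row.

Clock-valued diary variables (`"HH:MM"` strings) are deliberately left
categorical at ingestion; the feature catalog extracts their numeric
content (minutes after midnight, signed shortest-path differences across
midnight) where a clinical contrast is defined.  This avoids imposing a
circular-mean convention on a generic aggregation step.

## Transformation

* **Windows** are half-open `[origin + i·w, origin + (i+1)·w)` in whole
  days; timestamps bin by calendar date.  The default origin is each user's
  first touchpoint date (journeys align at enrolment); a fixed calendar
  origin is available for cohorts recruited on a common date.
* **Within-window aggregation** defaults: numeric → mean, categorical →
  mode, event → sum.  Mode ties resolve to the earliest-observed value in
  the window, making aggregation deterministic.
* **LOCF** (`carry_forward`) fills gaps after a user's first observation of
  a flagged variable — the treatment for questionnaires administered before
  each core.  Cells before the first observation stay missing: inventing a
  pre-baseline value would leak the baseline backwards.  The operation is
  idempotent.
* Only `(user, window)` pairs holding at least one touchpoint are
  materialised; `JourneyTable.to_dense_grid()` expands to the full per-user
  grid when rolling features need evenly spaced rows.
* **User-level aggregation** applies a per-variable aggregator (mean /
  mode / sum / last) over the user's windows, skipping missing cells.
  `last` means the last *observed* value.

### Per-core eligibility

At cutoff core `c`, users who completed core `c` are eligible and their
touchpoints are truncated at the core-`c` completion date.  The programme's
observed participation sequence declines monotonically under this rule,
matching the eligible-N shape such intervention studies report.  Users who
dropped before completing core `c` are excluded from the core-`c` analysis;
they are not distinguishable from still-active slow users without an
explicit dropout date, which real logs rarely carry.

## Feature engineering

Rolling features operate over `w` consecutive *observations*, not calendar
days (a calendar-day variant only requires densifying the grid first).
The sample (n−1) standard deviation is used; at `w = 1` it is undefined and
reported missing rather than zero.

The shipped catalog has 25 entries (8 summed daily indicators/gaps, 12
last-observation features including the six per-core completion latencies
and their running average, 5 diary-day means).  Entries referencing a
variable absent from a log yield an all-missing column with a warning, so
one catalog serves intervention logs of varying richness.  *Days since last
contact* is user-aggregated by **sum** as the catalog defines it, which
weights long silences quadratically; `last`/`max` aggregators are available
but non-default.  Interaction terms default to explicit pairs — all-pairs
expansion squares the feature count and is rarely wanted.

## Missing data

Deletion uses a *strictly greater than τ* rule, so a feature at exactly the
threshold survives.  Retained sets therefore nest as τ grows.  Protected
(catalog) features are exempt from deletion but still imputed.

KNN imputation (default `k = 5`) needs a distance on mixed-type rows with
missing entries; the package uses a Gower-style construction: numeric
dimensions contribute `|z_i − z_j|` on column-standardised values
(zero-variance columns contribute 0), categorical dimensions a 0/1
mismatch, averaged over the dimensions observed in *both* rows; rows
sharing no observed dimension are maximally distant.  Neighbour ties break
by row order.  A missing cell with no eligible neighbour falls back to the
column median/mode, logged.  All-missing columns are dropped (logged)
before imputation since no imputer can fill them.

## Models and validation

Four families: logistic regression (L1 via liblinear, L2 via lbfgs), SVM,
and gradient-boosted trees.  Numeric features are standardised inside the
fold pipeline for the margin-based learners and passed through for trees;
categoricals are one-hot encoded with the encoder fit on training folds
only, folding levels rarer than 5% into a single bucket so high-cardinality
columns (clock strings) cannot explode the design matrix.  Shipped default
grids: `C ∈ {0.01, 0.03, 0.1, 0.3, 1, 10}` for both logistic penalties;
`C ∈ {0.1, 1, 10} × {linear, rbf}` for SVM; trees `{100, 300, 500} × depth
{2, 3, 4} × learning rate {0.05, 0.1}`.

Stratified 10-fold CV is the default; every row is scored exactly once
out-of-fold, per-fold positive counts differ from the ideal by at most one,
and a single-class validation fold records a missing AUC with a warning
(the mean is over defined folds).  Hyperparameters are selected by mean CV
AUC on the same split (ties keep the first grid entry); this is tuning and
evaluation on one split, which is optimistic relative to nested CV — the
cross-validated error is reported as such and no holdout is taken by
default.  SVM scores are raw decision-function margins: AUC is rank-based,
so probability calibration would not change it.

AUC is computed as the Mann–Whitney pair statistic via average ranks (tie
half-credit); PRAUC as the average-precision step sum, reported beside its
chance level, the positive prevalence.  Imputation and deletion run inside
each per-core analysis, not globally, so later cutoffs cannot inform
earlier ones.

## Attribution

Shapley values are interventional: absent features are replaced by values
from a background sample of training rows.  Exact mode enumerates all
`2^m` coalitions (feasible to `m = 12`) and averages over every background
row; sampled mode averages marginal contributions over random feature
orderings with one background row per draw.  Both satisfy local accuracy
(`Σφ + base = score`) — exactly, because each sampled ordering telescopes.
Explanations are computed for out-of-fold instances, each against the model
that held it out, matching the evaluation posture.  Positive φ pushes
toward the dropout class (the positive class); rankings use mean |φ| so the
sign convention does not affect importance.  The reported top-k is 5.

## Synthetic cohorts

The simulator emulates the *structure* of a 7-core, 7-day-release
internet intervention: baseline questionnaires at day 0, daily logins with
sleep-diary entries on login days, automated reminder emails after three
silent days, trigger events on a quarter of login days, per-core
availability/completion milestones, and a dropout process.  Per user:

* latent engagement `η ~ N(0,1)`;
* daily login `~ Bernoulli(logistic(a₀ + b_login·η))`, `b_login = 1`;
* days to complete a core: geometric with mean `3·exp(−η)` (disengaged
  users are slow, so observed latencies are an engagement readout);
* while working on core `c` the user abandons with probability
  `logistic(c0 + 0.3·c − b_drop·η + b_lat·latency)`.

The rising per-core baseline (`+0.3/core`) mirrors the late-programme
attrition pattern implied by declining eligible-N sequences in such
programmes, and keeps the final-core analysis from degenerating to a
handful of positives.  Baselines `c0` are calibrated by bisection
(`calibrate_dropout_rate`) so each preset realises ≈ 39.7% dropout — the
complement of a 60.3% completion rate — and are frozen in the presets
(`null` solves its rate in closed form since no user effects enter).
Diary *values* are user-level offsets plus noise, independent of η: the
dropout signal flows only through logins, latencies and the hazard, so
attribution tests can check that the latency features, not the diaries,
carry it.  `b_drop = b_lat = 0` (`null` preset) removes all recoverable
signal.

Per-user RNG substreams (traits / core progression / daily observations)
derive from the master seed, so trajectories are stable when the cohort
grows and the labels-only fast path (`simulate_outcomes`) agrees exactly
with the full generator.

What the simulator does **not** emulate: real covariate distributions,
demographics, clinical response to treatment, informative missingness, or
any time-varying engagement dynamics (η is static).  Passing
signal-recovery tests therefore shows the *pipeline* recovers a planted
engagement signal of realistic size through the full transformation — not
that any particular AUC is attainable on real trial data.

## Validation experiment sizes

The standing experiments (`userjourney.experiments`) run the full
simulate→transform→impute→cross-validate path at the final pre-outcome
core: 20 replicates of null cohorts at n = 1000 (expect chance-level mean
AUC) and 20 replicates of signal cohorts (`b_drop = 1.5, b_lat = 0.3`) at
n = 500 (expect mean AUC ≥ 0.75 with completion-latency features in the
attribution top-5 in ≥ 80% of replicates).  These sizes keep a full
validation run in the minutes range on a single CPU while leaving the
stochastic checks well-powered; the replicate driver uses an L2 logistic
model with a small C grid — at the ~6% final-core prevalence (~20
positives) the boosted trees are the weaker, slower choice, as replicate
comparisons during development showed.

## Known limitations

* The regression branch (continuous outcomes, RMSE/MAE) is reserved in the
  configuration but not implemented.
* Hyperparameter tuning is not nested within the evaluation folds (see
  above); reported CV AUCs are mildly optimistic.
* Attribution explains a subsample of instances with Monte-Carlo Shapley;
  rankings on near-collinear feature families (e.g. the login-derived
  indicators) split credit across the family.
* Sub-daily windows are supported by the engine but untested against any
  shipped scenario.
* No time-lagged cross-feature engineering (e.g. relations between
  variables across windows); the rolling statistics are per-variable.
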