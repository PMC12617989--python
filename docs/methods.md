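# Methods

This note records the models, procedures and numerical choices behind
`gapbench`, and what its synthetic experiments do and do not establish.

## Synthetic cohort model

Each intubation event carries a latent **severity** process on the 4-hour
window grid: a stationary AR(1) with coefficient 0.9 and unit marginal
variance.  Every time-varying variable `v` loads linearly on severity with
loading λ_v (drawn from `latent_loading_range`, default [0.2, 0.6]) plus
an independent AR(1) idiosyncratic component.  The idiosyncratic AR
coefficient is solved so that the variable's *marginal* lag-1
autocorrelation equals its target ρ_v drawn from `ar1_range` — severity
mixing does not distort the per-variable autocorrelation users configure,
and parameter-recovery tests hold to ±0.05.  Binary variables are
thresholded latent Gaussians (prevalence drawn in [0.15, 0.85]);
categorical variables are latent Gaussians binned at Dirichlet-drawn
quantile cutpoints — autocorrelation stays meaningful for every variable
kind.

Raw observations are emitted at per-variable cadences of 1–4 h with
jittered timestamps and small measurement noise (`noise_sd`, default 0.05
on the latent scale), so windowing has real work to do.  Statics (age,
sex, race, admission measures) are constant within an event; admission
measures load weakly on mean severity so imputers have cross-variable
signal.  Durations are log-normal with μ = log(median) and σ solved from
the IQR ratio (defaults: median 4.4 days, IQR 2.2–8.5 days).  Ages are
log-normal (median 4.3 y, IQR 1–12.1), clipped to the >30-day, <18-year
eligibility band.

The binary outcome (successful extubation, i.e. no reintubation within
48 h) follows a logistic model on the mean severity of the last three
windows; the intercept is solved by bisection against the configured
prevalence target (default 76.1%) using the cohort's own severity sample,
so realized prevalence is on target up to Bernoulli noise.  Non-success
events receive a category (reintubation, death, tracheostomy, transfer,
tube change) at fixed census proportions, then collapse to "not success"
for modeling.  The continuous outcome is a systolic-blood-pressure
percentile series emitted directly as a time-varying variable
(`center + scale·z`, clipped to [1, 99]); the label at window k is its
value at window k+1.  The percentile reference computation itself is out
of scope — percentiles are generated, not derived from raw pressures.

**What the generator does not emulate:** clinical units and reference
ranges, pharmacology, documentation artefacts (charting duplication,
batch entry), inter-variable causal structure beyond a single severity
factor, and real missingness processes.  Passing tests therefore
establish that the *pipeline machinery* behaves correctly and that
structural results (calibration, mechanism signatures, error orderings
driven by autocorrelation) reproduce — not that any clinical conclusion
transfers to real data.

## Windowing

Windows are half-open intervals `(intubation + 4(k−1) h, intubation +
4k h]`, indexed from 1.  Numeric and binary cells take the in-window
mean (binary cells hence become fractions); categorical cells take the
mode with ties broken toward the most recent observation (the latest
assessment wins).  A cell is missing iff no in-window observation.  The
first two windows exist only to supply lags; the first modeling window
ends 12 h after intubation.  Events intubated ≤ 24 h are excluded.  A
partial final window (< 4 h before extubation) is kept if it has any
observation and flagged.  Binary labels at window k read the event state
at the end of window k+3; when that horizon passes the event's end the
terminal outcome is used (the status thereafter is the terminal status).
The wide matrix carries each time-varying variable plus two lagged
copies as distinct columns (265 features under the default census); lag
cells inherit the base window's value and missingness exactly, because
amputation precedes lag construction.

## Completion

The complete ground-truth table is built in a fixed order — linear
interpolation of interior gaps on the window index (numeric and binary),
nearest-observed fill with ties to the earlier value, deterministic
formula rules for never-observed variables (endotracheal tube size =
age/4 + 4), and finally random-forest donor imputation in self-fit mode.
Categorical series skip interpolation (undefined between levels) and go
straight to nearest fill, which preserves level validity.  Observed cells
are never altered; each stage weakly reduces the missing-cell count; the
per-cell provenance code (observed / interpolated / nearest / formula /
model) is retained for the originally-missing stratification.  Structural
gaps (windows that simply received no observation) are completed before
the "original missingness" stage so the amputer always starts from a
complete table; in two-stage mode they are folded into the
originally-missing flags.

## Amputation

Five variable groups (partitioning the amputable variables) define five
missingness patterns.  For each pattern, every row gets a weighted sum of
column z-scores (table mean/SD; categorical columns scored on level
codes): weight ratios observed:amputed are 1:0 (MAR), 2:1 (weak MNAR),
1:1 (moderate), 0:1 (strong); MCAR ignores the scores.  The outcome
enters with unit weight in all non-MCAR mechanisms.  Scores map to
per-row probabilities via `logistic(z + c)` with the offset solved by
bisection so the mean probability hits the per-pattern target; the target
is uniform across patterns and chosen so the expected *cell-wise*
proportion over the whole table equals `level × base_cell_proportion`.

Each pattern draws its own independent Bernoulli per row, so one row may
be hit by several patterns.  A single-pattern-per-row assignment would
cap the attainable cell proportion at one fifth under a five-group
partition, which cannot reach the 2× level (36.4%); independent
per-pattern draws reach any proportion up to the amputable fraction of
the table, while preserving the mechanism semantics carried by the
scores.  Because the per-row uniforms are drawn identically at every
level for a fixed seed, masks are nested across levels — the 2× mask
contains the 1× mask — which makes level-monotonicity comparisons paired
rather than independent.  Requested proportions beyond the amputable
fraction raise an error rather than clipping.

## Imputation strategies

All imputers are estimators with `fit(X)` / `transform(X)` /
`transform_multi(X)`; fitted state derives from training rows only, never
contains the outcome (fit refuses label columns), and supports single-row
application — the transfer contract required for real-time prediction.

* **mean** — unconditional training mean (numeric) or mode (categorical).
* **locf** — per-event forward fill on the base window series, after
  which lags are rebuilt (LOCF is defined on a time series, not on wide
  columns); values carry forward indefinitely; leading gaps stay missing
  unless the mean-fallback flag is set for complete-input outcome models.
* **none** — explicit passthrough for natively missing-capable learners.
* **rf_donor / bayes_pmm / lasso_boot** — chained equations on the
  training matrix: initialize at training means/modes, visit incomplete
  variables in ascending-missingness order, five sweeps (all
  config-exposed); the final sweep's per-variable models plus donor pools
  are the stored state.  Application replays the sweeps with stored
  models only.

Per-variable engines: the random forest (10 trees, `mtry = sqrt(p)` per
split — matching the ranger-style default of the chained-equations
software this design follows; sklearn's own regression default of using
all features makes the method substantially and unrealistically stronger)
routes a row down every tree, pools the union of training observations in
the reached terminal nodes and samples one donor's observed value.  The
Bayesian linear model uses a conjugate normal–inverse-gamma posterior on
standardized predictors with ridge `1e-4·n`; matching is on absolute
prediction difference, target predictions use posterior-draw coefficients
and donor predictions the posterior mean; one of the `k_donors = 5`
nearest donors is sampled, so imputations always lie in the observed
range.  Bootstrap LASSO fits one penalized model per imputation on a
bootstrap sample (fixed standardized penalty `alpha = 0.01`) and draws
prediction + Gaussian residual; two-level factors use an L1 logistic
draw, multiclass factors a depth-5 classification tree sampled from leaf
class frequencies.  Categorical PMM matches on integer level codes, so
imputed levels are always valid observed levels.

Because windowed binary variables are means of 0/1 observations, they are
numeric downstream; only true multi-level factors take the categorical
paths.  `max_predictors` (correlation-based predictor trimming) and
`max_fit_rows` (training-row subsampling for per-variable fits) are speed
levers, off at full scale and set to 20/800 in the desk preset.

`average_imputations` combines m completions cell-wise (mean / mode);
`mi_ensemble_predict` averages m outcome models' predictions — the two
ways multiple imputation feeds a prediction model.

## Outcome models

Gradient boosted trees (LightGBM) accept missing cells natively; L1
linear/logistic models refuse them, mirroring why imputation is mandatory
for linear learners.  Both tune by 5-fold cross-validation with folds
grouped by event (one event's windows never straddle folds), on training
rows only.  Binary tasks weight samples by inverse class frequency so
each class carries equal mass.  The default grid is small and printed in
config (learning rate {0.05, 0.1}, leaves {15, 31}, 200 trees; penalty
grids for L1); the classification threshold is 0.5, config-exposed.

## Evaluation

Imputation error is scored only at amputed cells against the complete
table: per-variable mean squared error after dividing by the variable's
complete-data SD (zero-SD variables excluded with a warning), and
per-variable classification error for factors; a dataset's error is the
unweighted mean over variables with at least one amputed cell (matching
a per-variable rather than cell-pooled summary).  Prediction metrics are
the standard set with balanced accuracy = (sensitivity + specificity)/2;
AUC is reported absent for single-class test labels.  The coefficient of
variation (sample SD / mean) is taken across imputation methods per
model × outcome × metric, pooling scenarios into per-method means; the
overfit gap is metric(train) − metric(test) per dataset.  The AR(1)
estimator is the pooled within-event lag-1 Pearson correlation with
boundary pairs dropped.  The originally-missing stratification reports
error separately for cells whose "truth" was itself constructed during
completion — the per-variable pooled MSE is exactly the cell-count
weighted mean of the two strata.

## Seeds and problem sizes

Every stochastic component takes a seed; the orchestrator derives child
seeds from the master seed and the (outcome, scenario, replicate, method)
path via CRC-hashed `SeedSequence`s, so any experiment cell reproduces in
isolation and a rerun is byte-identical.  Tests and the acceptance script
run at desk scale — a reduced census (about 15 variables), 30–60
patients, m = 10 imputations, 10–20 replicates — sizes chosen so the
statistical checks have adequate power while a full run stays laptop-
sized; the full-scale preset (886 patients, 99 variables, m = 30, 20
replicates, MI-ensembling on) ships as `paper_config()`.

## Known limitations

The generator is linear-Gaussian at heart; real EHR series have jumps,
documentation artefacts and informative measurement timing that it does
not model.  MAR scores can touch variables another pattern removed in the
same row (a consequence of independent per-pattern draws).  LOCF's
advantage on temporally stable variables is reproduced qualitatively; the
magnitude of any method gap at desk scale should not be read as an
estimate of the corresponding full-scale gap.
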