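# Methods

## The model

Weighted quantile sum (WQS) regression summarizes the joint association
of c correlated exposures with an outcome through a single empirically
weighted index.  Each exposure is scored into q quantile groups
(0..q-1); the model is

    g(mu) = beta0 + beta1 * sum_i w_i q_i + z'phi,

with the weights on the simplex (w_i >= 0, sum w_i = 1) and beta1
constrained to one sign, so beta1 reads as the outcome change per
simultaneous one-quantile-group increase of the whole mixture in that
direction.  Estimation is two-step: weights are estimated on a training
split in a bootstrap ensemble and averaged with a signal function, and
the resulting fixed index is tested in an ordinary GLM on the
validation split.

The two-index extension (2iWQS) estimates a harmful and a protective
index in one model,

    g(mu) = beta0 + beta1p * sum_i wp_i q_i + beta1n * sum_i wn_i q_i + z'phi,

with beta1p >= 0 and beta1n <= 0 and a separate simplex weight vector
per direction, all estimated jointly.  Two devices control the
collinearity between the indices (both are built from the same
exposures):

1. an L1 shrinkage on the raw weight parameters that zeroes the null
   components whose noise feeds the inter-index correlation, and
2. tolerance-weighted ensemble averaging — each bootstrap's weight
   vectors enter the average with signal (tol_b / sum_b tol_b)^k, where
   tol_b = 1/VIF of that bootstrap's index pair, so bootstrap solutions
   with less entangled indices count more.  If either final-model VIF
   exceeds 5 the exponent k is increased (re-averaging the stored
   bootstrap weights, up to k = 6) and the model is refit on the
   validation split.

If no bootstrap yields a nonzero coefficient in one direction, the
model falls back to the single-index WQS regression for the other
direction and logs a warning.

## Parametrization and the penalty

Weights are parametrized as w_i = v_i^2 / sum(v^2), which enforces the
simplex constraints without constrained optimization.  The printed
penalty form lambda * sum|v_i| is ill-posed under this substitution:
the loss depends on v only through w, which is invariant to rescaling
v, so the infimum over the scale sends the penalty to zero without
changing the fit.  The package therefore evaluates the penalty on the
unit-normalized v, equivalently

    penalty = lambda * sum_i sqrt(w_i),

which is scale-invariant, well-defined, and equals the printed form on
the unit sphere.  Note sum sqrt(w) ranges from 1 (one-hot) to sqrt(c)
(uniform), so the penalty rewards sparsity; because d sqrt(w)/dw
diverges at 0 it prunes small weights aggressively — more aggressively
than an L1 penalty on w itself would.

## Optimization

Fits minimize the penalized loss (residual sum of squares for the
identity link, binomial deviance for the logit link) by L-BFGS-B with
analytic gradients; the sign constraints on beta1/beta1p/beta1n are box
bounds.  Numerical choices:

* |x| is smoothed as sqrt(x^2 + eps) with eps = 1e-6 inside the
  optimizer; public objective functions use the exact value.  Fitted
  weights below 1e-6 are reported as exactly 0.
* The scale invariance of the objective in v leaves a zero-curvature
  ray that stalls quasi-Newton updates, so the internal objective adds
  a gauge term (||v||^2 - 1)^2 that pins the irrelevant scale; it is
  zero at the solution shell and does not affect the weights.  Reported
  objective values exclude it.
* Convergence means the optimizer's own success flag plus a projected
  gradient below 1e-4 relative to the objective scale; a failed fit is
  restarted once from the uniform 1/c weights.
* beta1 = 0 with the sign bound is a saddle: the gradient with respect
  to every v_i vanishes there, so a fit can terminate at zero even
  when directional signal exists.  When that happens the fit is
  retried from starting weights proportional to the positive part of
  the per-component marginal slopes (in the requested direction).
* Bootstrap fits are warm-started from one fit on the unresampled
  training split; the starting |v| is floored at 10% of its RMS so a
  component shrunk to zero on the full split can re-enter in a
  bootstrap resample.
* A bootstrap contributes to a direction's average only if its fit
  converged and |beta1_d| > 1e-8 (the weights are unidentified at
  beta = 0).

The starting values for the joint two-index fit come from two
single-index WQS regressions (one per direction) fit on all
observations without splitting or bootstrapping, started at v = 1; a
starter that fails or sticks at beta1 = 0 contributes the uniform 1/c
start instead.

## Validation step, standard errors, AIC

The validation model regresses the outcome on the fixed index (or
index pair) plus covariates.  The two-index validation GLM keeps the
sign bounds active (bound-constrained maximum likelihood); when a bound
is active the Wald standard errors, taken from the observed information
at the solution, are conditional on it and a warning is logged.
p-values are two-sided Wald without multiplicity adjustment.  AIC is
-2 log L + 2k with k counting the mean parameters plus, under the
identity link, the residual variance.

## Shrinkage selection

Candidate lambdas are scored by the mean validation-model AIC over a
(small) number of repeated holdout splits, all candidates sharing the
same split seeds; the minimizer wins, ties toward less shrinkage.  Two
entry points exist: the magnitude rule (grid {M/10, M, 10M} around the
order of magnitude M of the unpenalized fit's AIC, optionally refined
at {M/2, 5M}) used by the CLI pipeline, and the geometric scan
{0, 1, 10, ..., 1e4} used by the simulation benchmark.  Both extend
the grid a decade at a time while the best value sits on a boundary (a
rough bisection), and can evaluate one extra candidate at the geometric
mean of the winner and its better neighbor.

## Repeated holdout

Single-split WQS estimates depend on an arbitrary random partition, so
the whole procedure (split 60/40, stratified by outcome under the
logit link; bootstrap ensemble; validation model) is repeated H times
and summarized by the median and the 2.5th/97.5th percentiles (linear
interpolation between order statistics) of the per-split estimates.
Per component and direction the median weight is compared with the 1/c
threshold to call the mixture's important members; an index is called
significant when its percentile interval excludes 0.  Defaults are
H = B = 100 (full-scale analyses); the simulation profiles use
H = B = 50 or 20 to bound runtime.

## Quantile scoring

Quantile boundaries are inverted-CDF empirical quantiles; a value equal
to a boundary goes to the lower class; scores are 0-based.  Scores
depend only on ranks, so any strictly monotone transform of a column
leaves them unchanged.  Columns with fewer than q distinct values, or
any missing values, are rejected (complete cases only; no imputation).

## Synthetic data and the benchmark

The generator draws exposures from a multivariate normal distribution
with a chosen correlation matrix (from file, or synthetic exchangeable/
block families; the halved variant multiplies off-diagonals by 0.5 and
repairs indefiniteness by eigenvalue clipping), quantizes them, and
builds the outcome as Normal(beta0 + beta1p Q wp + beta1n Q wn,
residual_sd).  The default truth is a 38-nutrient mixture: five
harmful components (sodium 0.50, polyunsaturated fat 0.19, cholesterol
0.15, caffeine 0.10, calcium 0.07), ten protective ones (magnesium
0.27 down to alpha-carotene 0.05), coefficients +0.5/-0.5, no
covariates, intercept 0, unit residual SD.  The published weight
tables are rounded and sum to 1.01 per direction; they are renormalized
to the simplex.  What the generator does not emulate: the empirical
NHANES nutrient correlation structure (block patterns, a few strong
pairwise correlations up to ~0.88, mild negative ones), skewed raw
intake distributions (irrelevant after quantile scoring), covariate
confounding, and survey design.  Passing benchmarks on exchangeable
correlations therefore validate the estimator mechanics, not the
published field numbers.

The benchmark simulates R replicate datasets and compares: m1 — two
separate unpenalized single-index WQS regressions (one per direction);
m2 — the same ensembles but one joint unconstrained validation model;
m3 — quantile g-computation (the directional sums psi_pos/psi_neg of
the per-component GLM coefficients); m4 — the penalized two-index
model; m4_1d — a penalized single positive index.  Reported per method
and direction: the median over replicates of (estimate - truth), a
bootstrap SE of that median (1000 resamples), and for weight-producing
methods the average sensitivity/specificity of median-weight selection
at the strict 1/c threshold.  An absent direction (fallback) is read
as an estimated effect of 0.  A direction counts as "retained" in a
replicate when it is present in more than half the splits and its
percentile interval excludes 0.  Benchmark problem sizes default to
n = 2000 per replicate with H = B = 20 and R = 20 (R = 12/8 in the
acceptance script); the full-scale analysis sizes (n = 5960,
H = B = 50-100) are configurable.

## Known limitations

* Under an exchangeable correlation of 0.4 across all 38 components,
  the two estimated indices share a strong common component whenever
  the weights are dense, and collapse to one or two components when
  the penalty is strong.  The two-index coefficients are consequently
  inflated by roughly +0.15 in the dense regime (lambda <= 1) and
  attenuated by roughly -0.2 in the sparse regime (lambda >= 10 at
  n = 2000), and the AIC-selected lambda lands in the sparse regime.
  The near-unbiased sweet spot reported for the empirical nutrient
  correlation structure is not reproduced under this synthetic
  correlation; see the benchmark outputs for the measured values.
  With oracle (true) weights the validation model is unbiased, so the
  bias is attributable to weight estimation error interacting with the
  exchangeable design, not to the validation-step machinery.
* The tolerance-exponent escalation re-averages stored bootstrap
  weights only; it cannot repair an ensemble whose every bootstrap is
  collinear.
* Logit-link fits use the binomial deviance in place of the squared
  error; all other machinery is link-agnostic.  The simulation study
  generates Gaussian outcomes only.
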