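# Methods

## Model

An element (a subject, or one constant-label segment of a labeled time
series) is represented by the p×p covariance or correlation matrix Σ_i
of its p channels, together with the number n_i of time points behind
it. Under the working assumption that the observation vectors are
i.i.d. mean-zero Gaussian, the scatter matrix of n_i such vectors is
Wishart, M ~ W_p(n_i, Σ), with E(M) = n_i Σ. Each class C is summarized
by a single scale matrix Σ̂_C, the convex combination of its members'
matrices; scoring an element against two classes is a log-likelihood
ratio under the two class-parameterized Wishart laws, and deleting a
feature from both element and class matrices measures that feature's
contribution to the ratio. Because the degrees of freedom enter the
density explicitly, elements with different n_i are directly
comparable — no clipping, padding or resampling.

The density requires n ≥ p and an invertible scale. Both are enforced:
elements with n_i < p are rejected (or counted and dropped, per
policy), and scale matrices must pass strict SPD validation. This is
the method's hard applicability limit; it cannot score "wide" data.

## Scale conventions: `literal` and `scatter`

Two conventions are implemented for what the density is evaluated *at*:

* **literal** (default): the class density is evaluated directly at the
  element's matrix Σ_i under W(n_i, Σ̂_C). This is the method's original
  form and is kept as the default.
* **scatter**: the density is evaluated at the scatter matrix n_i·Σ_i.
  Since E[W(n_i, Σ̂_C)] = n_i Σ̂_C, this is the convention in which the
  likelihood argument and the class model live on the same scale; it is
  equivalent (up to class-independent terms that cancel in every ratio)
  to scoring Σ_i under W(n_i, Σ̂_C / n_i).

The distinction matters under uneven sampling. In literal mode every
score and every Ratio_j contains an additive term proportional to the
element's own n_i, with a coefficient set by the difference of class
log-determinants. Across a dataset with spread-out n_i this acts as a
per-element nuisance offset. When the two classes differ asymmetrically
across features a downstream linear classifier can cancel it, but in a
perfectly feature-exchangeable design (classes differing by a uniform
correlation level on all channels) the nuisance direction coincides
with the signal direction and classification from literal-mode ratios
degenerates to chance. Scatter mode makes the score a proper
log-likelihood ratio whose class signal *grows* with n_i instead of
being masked by it. Consequently: feature *ranking* works in either
mode; classification benchmarks in this package's validation suite use
scatter mode; literal remains the default, matching the method's
original formulation. Choose per run via `RunConfig.mode` / `mode = scatter`
in a config file.

## Estimation and exclusion

* Class scale: uniform mean or dof-weighted mean (weights n_i / Σ n_j).
  Default `dof_weighted`, which reduces to uniform when all lengths are
  equal. The average of SPD matrices is SPD; the result is re-validated.
* Degrees of freedom for scoring are always the element's own n_i; the
  class model stores none.
* Exclusion: `leave_one_out` (the element's own class is re-averaged
  without it; the other class keeps all members) or `k_fold`
  (stratified by label, shuffled with a mandatory seed; every class
  model for a fold is fitted on the fold's complement). Both guarantee
  zero weight for the scored element's matrix in its own class model,
  which the tests verify by reconstruction.

## Time-series handling

Series are split at every label change into maximal constant-label
batches; each batch of length T ≥ p yields one element with dof = T.
Batches are mean-centered per channel before covariance/correlation
extraction (the model assumes mean-zero vectors; raw physiological
signals carry large offsets). The covariance divisor is T, matching the
scatter convention (1/n)ΣXX′; T−1 is available via `ddof=1`. A
user-supplied `preprocess` hook can detrend or filter batch data before
extraction; no detrending is applied by default. Indices are 0-based,
intervals half-open.

Perfectly collinear channels produce a singular correlation matrix and
fail strict SPD validation; an optional ridge term ε·I (default ε = 0)
can be added before factorization. Zero-variance channels under the
correlation statistic raise an error rather than emitting NaNs.

## Numerical choices

* All density work in log space. Log-determinants come from Cholesky
  diagonals; tr(Σ⁻¹M) from triangular solves of the cached factors
  (‖L_Σ⁻¹ L_M‖_F²). No explicit inverse or determinant is ever formed.
* SPD validation: symmetry within `sym_tol` (default 1e−8, relative),
  symmetrize-and-store when within tolerance; positive-definiteness by
  attempted Cholesky with every squared pivot above
  `pd_tol · max diag` (default 1e−10). Cost: one factorization, reused
  by every later density evaluation of that matrix.
* The triangular factor A with AA′ = Σ used by the sampler is the
  Cholesky factor — the unique lower-triangular factor with
  non-negative diagonal for SPD Σ.
* Degrees of freedom must be integers (time-point counts); non-integer
  dof is rejected.
* Non-SPD density arguments return −∞ (the density is zero off the
  cone); they are never silently repaired.
* Every stochastic operation (sampling, fold shuffling, subsampling,
  synthetic generation) takes an explicit seed; there is no global
  random state.

## Synthetic data

The generator realizes the model's own generative assumption: each
element is an independent series of T_i ~ Uniform{L_min..L_max}
mean-zero Gaussian p-vectors with its class's covariance, L_min ≥ p so
every element is scoreable. A scalar `separation` interpolates class
B's covariance toward class A's (0 = identical classes, the
calibration null). `planted_feature_spec` builds feature-recovery
benchmarks: class B differs from white only on an informative block
(variance 1+effect, covariance `effect` between informative pairs).

Default study conditions used throughout the validation suite:
p = 5 (6 for planted-feature runs), 30 elements per class, lengths
40–80 (50–100 for planted runs), class pair identity vs
0.5·I + 0.5·J. Uniform integer lengths mimic the variable segment
lengths of state-segmented recordings; the distribution choice is a
harness decision.

What the generator does *not* emulate: temporal autocorrelation,
nonstationarity, heavy tails, line noise, artifacts — i.e. everything
that makes real EEG/fMRI hard. Passing tests establish correctness of
the computation and behavior under the model's assumptions, not
performance on real recordings.

## Validation design notes

* Null calibration compares the mean complete score to zero using the
  standard error **across independent replicates**. Within one
  replicate all elements share the same two fitted scale matrices, so
  their scores are strongly correlated and the across-element SE would
  understate the real variability by an order of magnitude.
* Classification benchmarks use a single pluggable classifier (linear
  C-SVM with standardized inputs by default; logistic regression and
  random forest available by name) rather than a classifier search:
  the object under test is the transformation.
* Cross-validation is stratified; 5 folds inside subsample-stability
  analyses, 10 elsewhere, seeds fixed.
* Problem sizes in the validation suite (≤ 60 elements, p ≤ 6, 50
  repetitions for recovery rates) were chosen so the full suite
  completes in well under a minute while keeping Monte-Carlo bands
  (3 SE / binomial at N = 60) meaningful.

## Known limitations

* n_i ≥ p is absolute; near-singular matrices need an explicit ridge.
* Correlation matrices are accepted as density arguments although they
  are not strictly Wishart-distributed (unit diagonals are a
  constraint); this mirrors standard practice for electrode
  correlation studies and is flagged by `is_correlation`.
* Literal-mode scores carry the n_i nuisance described above; prefer
  scatter mode when batch lengths vary widely and classes are close to
  feature-exchangeable.
* The multiclass path (per-class delta columns, no ratio) is provided
  but only the two-class ratio transform is benchmarked.
* Class models are refitted from scratch per fold; no online updating.
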