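# Methods

`harmonex` implements and compares methods that translate sum scores from a
short screening questionnaire onto the metric of a longer one when both were
answered by the same respondents (a single-group, common-persons linking
design). The concrete setting it models is a general-population child cohort
in which parents completed both a 5-item hyperactivity/inattention scale
(items scored 0/1/2, sum range 0–10; the *source*) and an 11-item attention
problems scale (sum range 0–22; the *target*). The goal is a mapping
`e: source score(s) → target-scale score` whose quality is judged by the
cross-validated RMSE between predicted and observed target sums.

## Synthetic data generator

Real paired data of this kind is typically access-restricted, so the package
ships a generative model that reproduces the statistical fingerprint such
cohorts show, and every downstream stage is developed and tested against it.

Responses follow the generalized partial credit model (GPCM). For an item
with discrimination `a > 0` and thresholds `b_1 … b_{K-1}`,

    P(X = k | θ) ∝ exp( Σ_{v≤k} a (θ − b_v) ),    k = 0 … K−1,

with the empty sum for `k = 0`; `b_k` is the trait level where categories
`k−1` and `k` are equally probable. Traits are standard normal. Two
scenarios are supported:

* **unidimensional** — one trait drives all 16 items (the regime the
  one-dimensional IRT crosswalk assumes);
* **correlated_traits** — source items load on trait 1, target items on
  trait 2, with corr(θ1, θ2) = 0.58 frozen in the fixture. This is the
  simplest generative model for two scales that measure correlated but
  non-identical constructs.

The fixture item parameters were calibrated once by simulation so that, at
n = 1551 (the cohort size emulated): Guttman's λ₂ is ≈ 0.80 for the source
scale and ≈ 0.82 for the target scale, both sum distributions are strongly
right-skewed with mode at/near 0 (a general-population sample has few high
scorers), the two-trait scenario yields a between-scale sum correlation of
≈ 0.43, and the banks are heterogeneous: discriminations range 1.3–2.9
(source) and 1.06–2.12 (target), and the target bank's thresholds sit
higher relative to its length, giving the two sum distributions visibly
different shapes. Heterogeneity matters: with exchangeable items the source
sum is nearly sufficient for the item vector, and item-level mappers could
not outperform sum-level ones — contrary to how real scales behave. After
calibration the parameters were frozen in
`src/harmonex/fixtures/cohort_items.json` and are never re-estimated.

One integer seed drives the generator; trait and response streams are
spawned from it via `numpy.random.SeedSequence(seed).spawn(2)`, making
datasets byte-reproducible.

**What the generator does not emulate:** item content and wording, reverse
coding, informant and age/sex effects, missingness (the emulated analysis
is complete-cases by design), cross-loadings, or item-specific correlated
errors. The last two are why passing results on synthetic data say less
about real cohorts than they appear to — see *Scenario choice* below.

## Equating methods

All four methods operate on the two observed sum-score distributions,
with zero-frequency scores kept in the support at probability 0.

* **Mean**: `e(x) = x − μ_s + μ_t`.
* **Linear**: `e(x) = (σ_t/σ_s)(x − μ_s) + μ_t`; matches mean and SD
  exactly (moments use the n−1 convention, configurable).
* **Equipercentile**: percentile ranks are continuized by spreading each
  integer score uniformly over `(x−0.5, x+0.5)`, so
  `PR(x) = 100·(F(x−1) + f(x)/2)` at integers; the inverse is the standard
  `y* − 0.5 + (p − F_t(y*−1))/f_t(y*)` with `y*` the smallest target score
  whose CDF reaches `p`. Tie rule: when `p` lands exactly on a CDF plateau
  spanning zero-frequency target scores, the midpoint of that run is
  returned (deterministic, matches the common convention).
* **Gaussian kernel (single-group)**: each discrete score distribution is
  continuized by `F_h(x) = Σ_j r_j Φ((x − a_h x_j − (1−a_h)μ)/(a_h h))`
  with `a_h = σ/√(σ² + h²)`, which preserves the discrete mean and
  variance; `e(x) = G_h⁻¹(F_h(x))` is strictly increasing. The bandwidth
  minimizes the squared distance between the continuized density and the
  relative frequencies at the support points, over 61 log-spaced values in
  [0.05, 3]; the chosen h is recorded in the function's metadata. The
  paired (same-persons) design enters through the data contract — both
  marginals come from the same respondents — and optionally through
  bivariate log-linear presmoothing of the joint score table
  (`bivariate_presmoothing=True`; marginal polynomial degree 3 plus one
  cross-product term). The default presmoothing is none (empirical
  frequencies); univariate polynomial log-linear presmoothing of degree d
  is available.

On the small-bandwidth limit: at integer support points `F_h → PR/100`
exactly, but the inverse of a near-discrete target CDF snaps to the jump
locations, so `e_kernel → e_equipercentile` pointwise only where source and
target percentile ranks align (notably self-equating, where both are the
identity). The tests exercise exactly that aligned case; for differing
distributions the two can differ by up to half a score point at small h.

Equated scores are kept real-valued (concordance values are not round
numbers); rounding is a separate optional step. Scores outside the observed
source range are extrapolated linearly with the boundary slope, logged, and
clamped to the target range on application.

## IRT crosswalk

The unidimensional GPCM is fitted jointly to all 16 items by marginal
maximum likelihood EM. Numerical choices: 61 equally spaced quadrature
nodes on [−6, 6] with standard-normal weights (this also fixes the latent
scale; estimates are not rescaled); E-step posteriors computed in log
space; M-step updates each item's `(a, b₁, b₂)` by L-BFGS-B with analytic
gradients of the expected complete-data log-likelihood, warm-started at the
current values — the quasi-Newton line search cannot return a worse point,
so the marginal log-likelihood is non-decreasing across cycles (asserted in
tests to 1e−8 slack). Starting values: `a = 1`, thresholds at normal
quantiles of the cumulative observed category proportions. Convergence:
maximum absolute parameter change < 1e−4, cap 500 cycles. A category that
is unobserved in a training fold is an error by default, naming the item;
`on_empty_category="collapse"` merges it into its lower neighbor for
fitting, and scoring then uses the surviving category values.

Harmonization is the two-step crosswalk: an expected a posteriori (EAP)
trait estimate from the source items under the N(0,1) prior, then the
model-expected target sum `Σ_items Σ_k k·P(k|θ̂)` — a composition of
monotone maps, bounded by the target range, real-valued (not rounded before
RMSE; the comparison deliberately preserves each method's native output
type). The GPCM is refitted inside every training fold.

## Machine-learning mappers

Six methods — linear regression, cumulative-logit ordinal regression,
support-vector regression/classification (linear kernel, C = 1, ε = 0.1),
and random-forest regression/classification (500 trees, default mtry) —
are applied in up to three mapping settings: sum→sum (only for linear and
ordinal regression; a single predictor is not sensible for forests or
SVMs), items→sum, and items→items (one sub-model per target item,
predictions summed; per-item regression outputs are not rounded before
summing by default). Together with the two equating methods (sum→sum) and
the IRT crosswalk (items→sum), the registry enumerates exactly 17 valid
method × setting combinations.

Hyperparameters are the wrapped libraries' defaults except where noted;
all stochastic methods are seeded from the pipeline seed. Ordinal
regression predicts the modal category by default (hard prediction — the
rounding behavior that penalizes ordinal approaches on an interval-like
target); `soft_labels=True` switches to the expected category. The
classification forest on ordered labels likewise predicts the
majority-vote class by default; score-based aggregation (expected label,
rounded) is available behind the same flag but is not the default because
it makes the classification forest statistically indistinguishable from
the regression forest, erasing the regression-vs-classification contrast
the comparison is designed to expose. The specialized ordinal-forest
algorithm is not reimplemented. Classification label spaces are the
categories observed in training (predictions therefore stay within the
bounded scale).

## Evaluation

The direction of harmonization follows reliability: the scale with the
higher Guttman λ₂,

    λ₂ = (σ_X² − Σ_j σ_j² + √(m/(m−1) · Σ_{j≠l} σ_jl²)) / σ_X²,

keeps its metric (criterion); ties go to the longer scale and are logged.
λ₂ is never below Cronbach's α (property-tested against an independent α
implementation). Variance convention: n−1 throughout, configurable.

The comparison uses 5-fold cross-validation (80% train / 20% test), fold
sizes differing by at most one, assignments drawn once per run and shared
across all combinations so split noise does not confound the method
comparison (a flag redraws folds per combination). Per combination and
fold, RMSE = √(mean (observed − predicted)²); summaries are the median,
mean and SD over the five folds. Observed-vs-predicted pairs are retained
for one fold (or all) for scatter-style diagnostics. A failing combination
is recorded and skipped without aborting the run. An injectable
oracle mapper that returns the observed target sums verifies the loop's
plumbing (its RMSE must be exactly 0), and a mutation test verifies that
held-out rows cannot influence any fitted state.

## Scenario choice for the replication checks

The qualitative result pattern this package is built to reproduce — item
-level regression beating sum-level equating, kernel beating linear
equating, regression beating classification, and the IRT crosswalk sharing
the best tier with linear regression and the regression forest — is
checked on five cohort-scale generator runs in the **unidimensional**
scenario. The reason is instructive. Equating functions and the IRT
crosswalk are *concordance* maps: they place scores on the target metric
with (approximately) the target's full spread. The conditional mean
E[target sum | source data], which minimizes RMSE, has its spread shrunk
by the strength of the source–target relationship. Under the two-trait
scenario at sum correlation 0.43, that shrinkage factor is severe, the
conditional mean is nearly linear, and every full-spread map — linear
equating, kernel equating, and IRT alike — pays a large, nearly identical
RMSE penalty: kernel no longer separates from linear equating, and IRT
trails the regressions by ~0.25. The reference pattern, in which the IRT
crosswalk ties the best regressions, can only arise when the single-factor
model approximately holds for the joint item pool — which is how such
cohorts tend to behave in practice, cross-loadings and shared method
variance pulling the joint item pool toward a dominant dimension. The
two-trait
scenario is therefore kept as the default for *marginal* emulation (it
reproduces the observed between-scale correlation) and reported alongside,
while the ranking replication runs where the ranking's own precondition
holds. Equivalently: a clean two-factor simple structure at ρ ≈ 0.58 is
demonstrably *not* a model under which the reference ranking can arise,
and results computed under it say so.

## Problem sizes and determinism

Tests run the comparison at n = 1551 with 5 folds over 5 generator seeds,
the parameter-recovery check at n = 2000, and component tests on toy
distributions or n ≤ 900 samples; these sizes keep the full suite and the
acceptance script comfortably reproducible on a single CPU. All randomness
flows from explicit integer seeds; repeated runs are bit-identical.

## Known limitations

* No anchor-item (common-items/NEAT) designs, no standard errors of
  equating, no log-linear model selection.
* The ordinal forest is approximated by a seeded classification forest on
  ordered labels, not the specialized algorithm.
* EAP scoring assumes the N(0,1) prior of the fitting run; fitted
  parameters are not rescaled or linked across runs.
* The generator's simple two-factor structure is a lower bound on realism
  for partially overlapping constructs; real item pools with cross-loadings
  can behave much closer to the unidimensional scenario (see above).
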