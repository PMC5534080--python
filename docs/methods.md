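# Methods

`survforest` implements three ensemble estimators of the conditional
survival function S(t | x) for right-censored data, a Weibull
proportional-hazards simulator with calibrated censoring, and the
IPCW-Brier-score machinery used to compare the estimators. This note
records the model conventions, the numerical choices, and the places where
a design decision was genuinely open.

## Data model

A dataset is the triple (T, δ, X): observed time T = min(T*, C), event
indicator δ = I(T* ≤ C), and a covariate matrix whose columns are typed
binary (0/1), polytomous (unordered categories), or continuous. Latent
event and censoring times are retained by the simulator for diagnostics
only; no estimator reads them.

## Simulation designs

Event times follow a Weibull proportional-hazards model. With shape θ and
linear predictor η = β₀ + Σⱼ βⱼxⱼ, the cumulative hazard is
H(t | x) = t^θ · exp(η), inverted as

    T* = λ · (−log U)^(1/θ),    λ = exp(−β₀/θ − Σⱼ βⱼxⱼ/θ),

so λ is the covariate-specific Weibull *scale*; θ = 1 yields exponential
times with mean λ. θ > 1 gives an increasing hazard, θ < 1 decreasing.

The built-in registry holds 22 designs in four families (6 binary, 6
polytomous, 6 mixed, 4 with interactions) spanning n = 100–2000 and
censoring targets of 20/50/80%:

* **Binary designs.** Ten Bernoulli covariates with fixed coefficient
  vectors, one per hazard trend: θ = 0.8 (β₀ = −0.98), θ = 1.5
  (β₀ = −1.44), θ = 1 (β₀ = 0.9). The Bernoulli probabilities are not part
  of the coefficient tables; pⱼ = 0.5 is used for all ten covariates as
  the natural symmetric default. Censoring times are Weibull with shapes
  0.4 / 2.4 / 1 for the three trends.
* **Polytomous designs.** Ten unordered covariates with 3/4/5 levels
  cyclically, equal sampling weights, and per-level coefficients evenly
  spaced on [−1, 1] — a deliberate many-split-point regime in which every
  covariate carries signal. Event shapes are 0.5 / 1.5 / 1; censoring
  shapes 0.4 / 1.2 / 1.1 per trend.
* **Mixed designs.** Five binary covariates (first five binary
  coefficients) plus five polytomous ones as above.
* **Interaction designs.** The mixed covariate set plus two product terms
  (coefficient ±0.7) between a binary covariate and the per-level
  contribution of a polytomous covariate.

**Censoring calibration.** The censoring Weibull scale is found by
bisection on log(scale) against a fixed Monte-Carlo probe of 10⁴ latent
event times and baseline censoring draws (dedicated probe seed, tolerance
0.02). Because the probe is fixed, the empirical censoring fraction is a
monotone step function of the scale and the search is deterministic. A
target of 0 returns an infinite scale (no censoring). Every built-in
design reproduces its tabulated censoring rate within ±2 percentage points
at n = 10⁴ (asserted in the test suite).

What the simulator does *not* emulate: the joint covariate dependence,
non-Weibull censoring, time-varying covariates, or the exact covariate
distributions of real cohorts such as demographic surveys. Passing tests
therefore demonstrate correctness of the estimators under a clean
proportional-hazards data-generating process, not performance on real
registry data.

## Survival trees

Trees partition the covariate space recursively with binary splits:
X ≤ c for ordered covariates, X ∈ A for level subsets of unordered ones
(exhaustive proper-subset search, refused above 8 observed levels).
Terminal nodes carry the Kaplan–Meier curve of their members.

Two split rules:

* **log-rank** — the standardized two-sample log-rank statistic between
  candidate daughter nodes (hypergeometric variance); the squared form is
  maximized.
* **log-rank score** — per-subject scores
  aₗ = δₗ − Σ_{k≤γₗ} δₖ/(N − γₖ + 1), where γ counts observed times ≤ Tₗ
  with events ordered before censorings at ties (tied subjects of equal
  status share a score). The statistic for a left group of size R₁ is
  |Σ_left aⱼ − R₁ā| / sqrt(R₁(1 − R₁/N)Sₐ²) with Sₐ² the (N−1)-denominator
  sample variance — exactly the permutation standard deviation of the
  numerator.

Admissibility: both children must contain at least `min_events` events
(default 3). A node is terminal below 2·`min_node_size` subjects (default
15) or 2·`min_events` events. At each node `mtry` covariates (default
⌈√p⌉) are drawn without replacement as candidates. Ties between equal
statistics break to the earlier candidate variable, then the earlier split
in canonical enumeration order, making tree growth reproducible.

## Random survival forests (RSF1, RSF2)

Each of `n_trees` trees (default 100) is grown on an independent bootstrap
sample of size N (with replacement). RSF1 uses the log-rank rule, RSF2 the
log-rank-score rule. Ensemble prediction averages the terminal-node
Nelson–Aalen cumulative hazards across trees and exponentiates, so curves
are proper (start at 1, non-increasing); averaging hazards rather than
survival curves follows the convention of the standard RSF software.
Out-of-bag prediction restricts the average to trees where a subject was
excluded by the bootstrap (expected OOB fraction e⁻¹ per tree). Unseen
categorical levels at prediction time follow the child with more training
subjects.

Permutation variable importance is the increase in out-of-bag integrated
Brier score after permuting one covariate column, averaged over `n_perm`
permutations — the same loss used for model comparison, so importance and
evaluation share a currency.

## Conditional inference forests (CIF)

Conditional inference trees separate variable selection from split-point
search. At each node the log-rank scores of the node's subjects are
computed once, and every candidate covariate is tested for association
with them by a linear rank test in the permutation framework: the
statistic vector (per-level score sums for categorical covariates, the
single weighted sum for numeric ones) is standardized by its exact
conditional mean and covariance, and summarized as the quadratic form
(T − μ)ᵀ Σ⁺ (T − μ) with a χ²_rank(Σ) reference. The quadratic form is
used rather than a maximum-of-components statistic because its p-values
are calibrated across covariates with different level counts — the
property that removes split-point-cardinality bias (an
independence-approximated max-abs reference measurably favours many-level
covariates under the null). For nodes smaller than 20 subjects the
asymptotic reference is replaced by a seeded Monte-Carlo permutation
p-value (1999 draws), whose resolution (5·10⁻⁴) is far below any stopping
threshold used. Selection takes the minimum raw p-value; the Bonferroni
adjustment over the candidates tested at the node governs stopping only.
(Selecting on the adjusted values would be equivalent except for their
clipping at 1, which would create artificial ties resolved by position —
itself a selection bias.)

Two conventions differ deliberately between single trees and forests,
mirroring the reference software:

* `grow_ctree` stops a node when the minimum Bonferroni-adjusted p-value
  exceeds α = 0.05 — the single-tree default, giving interpretable trees
  with per-node type-I error ≈ α (verified by a calibration suite).
* `fit_cif` grows forest trees with α = 1: variable selection stays
  p-value-based (hence unbiased) but recursion is limited by node size
  only, as in the reference conditional-forest defaults. Forest node-size
  floors are `min_node_size` = 10 and `min_events` = 2, slightly smaller
  than RSF's, because conditional trees are grown on 0.632-subsamples
  drawn without replacement whereas RSF trees see size-N bootstrap
  samples; the pairing mirrors the respective reference defaults
  (nodesize 15 for RSF versus minsplit 20 / minbucket 7 for conditional
  forests) so that neither ensemble is artificially shallower.

Prediction is a weighted Kaplan–Meier over the *training* set: a training
subject's weight is the number of trees in which it is in-bag and shares
the query's terminal node. Terminals with many subjects at risk therefore
contribute more total weight. With a single root-only tree this reduces
exactly to the ordinary Kaplan–Meier of the training data (tested).

## Prediction error

**IPCW Brier score.**

    BS(t) = (1/N) Σₗ [ Ŝ(t|xₗ)² I(tₗ ≤ t, δₗ=1)/Ĝ(tₗ⁻)
                       + (1−Ŝ(t|xₗ))² I(tₗ > t)/Ĝ(t) ]

with Ĝ the Kaplan–Meier estimate of the censoring survival function
(censorings as events; at tied times censorings are processed after
events, and the event term uses the left limit Ĝ(tₗ⁻), the standard IPCW
convention). Subjects censored before t contribute nothing. With no
censoring the formula reduces exactly to the uncensored Brier score
(tested), and a constant Ŝ = 0.5 scores 0.25 everywhere.

**Integrated Brier score.** Trapezoidal integral of BS(t) over the
evaluation grid divided by the grid span, so IBS ∈ [0, 1] and the 50%
uselessness bound is scale-free. The default grid is the unique event
times truncated at the 95th percentile of follow-up and wherever Ĝ > 0;
grids longer than 100 points are thinned to quantile-spaced event times
(the trapezoid integral is essentially unchanged and prediction cost is
bounded on large datasets).

**Boot632+.** For each of B bootstrap samples (default 5) every model is
refit on the in-bag subjects and scored on the out-of-bag ones; samples
whose out-of-bag part lacks events are redrawn. Pointwise, the estimate
combines the apparent error, the averaged out-of-bag error (capped by the
no-information error), and the no-information error obtained by scoring
every prediction against every outcome (the double sum factorizes, so it
is cheap); the relative overfitting rate R is clipped to [0, 1] and the
weight is w = 0.632/(1 − 0.368·R). The estimate therefore always lies
between the apparent and no-information error. Ĝ is estimated once on the
full sample.

## Benchmark configuration and scale

The three-way comparison is a comparison of *software configurations* as
much as of algorithms, and the stopping constants matter. `fit_rsf`'s
library defaults (`min_node_size` 15, `min_events` 3) are deliberately
conservative, matching the current convention of the standard RSF
software. The replication benchmark, however, configures RSF with the
deep-tree constants of the 2017-era survival-forest software
(`min_node_size` 3, `min_events` 1, i.e. nodesize 3 with no per-child
event floor): those are the defaults the original three-way comparison
ran under, and the split-point-cardinality overfitting that motivates
conditional inference forests only expresses itself when RSF trees are
grown deep. With regularized RSF trees the three models' errors are
near-identical on 3–5-level covariates. CIF always runs its reference
conditional-forest defaults (α = 1, mtry 5, minsplit 20).

The full comparison (22 designs × 3 models × 100 repetitions × 100 trees,
B = 5) is the production configuration of `survforest benchmark`. The
test suite runs a reduced configuration — polytomous and binary families
with sample sizes capped at 300, 5 repetitions, 50 trees, B = 5 — chosen
as the smallest scale at which the qualitative ordering of the models is
stable on medians; the acceptance assertions are therefore on medians and
interquartile ranges, not on absolute IBS levels. Absolute IBS values
depend on the evaluation grid and truncation, so they are comparable in
ordering between models, not in level across studies.

## Known limitations

* Exhaustive subset search is exact but exponential in the number of
  levels; covariates with more than 8 observed levels are refused rather
  than split heuristically.
* The χ² reference for the association test is asymptotic; below 20
  subjects a Monte-Carlo permutation p-value substitutes, but between
  ~20–40 subjects with heavy censoring the reference is approximate.
* Missing covariate values are not handled; complete cases are assumed.
* The no-information error uses the apparent-fit predictions, as in the
  cited estimator; models whose apparent fit is degenerate (e.g. a single
  root node) make the .632+ weight collapse toward the apparent error.
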