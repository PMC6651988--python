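# Methods

## The estimand and the synthetic-control model

The setting is a comparative case study on an annual panel: `J + 1` units
observed over years `t = 1 … T`, unit 1 treated from the policy year `T₀`
onward, units `2 … J+1` untreated donors. The outcome `Y_jt` is a bounded
share in percentage points (0–100). The causal effect in a post-policy year
is `α₁ₜ = Y₁ₜ − Y₁ₜᴺ`, where `Y₁ₜᴺ` is the outcome the treated unit would
have had without the policy.

The synthetic control estimates `Y₁ₜᴺ` by a convex combination of donors,

    Ŷ₁ₜᴺ = Σⱼ wⱼ Yⱼₜ ,   wⱼ ≥ 0,  Σⱼ wⱼ = 1,

with weights chosen to reproduce the treated unit's pre-policy
characteristics: `W` minimizes `(X₁ − X₀W)′ V (X₁ − X₀W)`, where the rows
of `X₁` (k×1) and `X₀` (k×J) are predictors — each covariate's pre-policy
mean and each selected pre-policy year's outcome — and `V` is a
nonnegative diagonal importance matrix normalized to sum 1. The implicit
identifying assumption is a factor structure: outcomes driven by common
time shocks plus a time-varying factor loading on unit-specific
characteristics, so that a donor combination matching the treated unit's
pre-policy path and covariates also matches its counterfactual post-policy
path. This relaxes the parallel-trends assumption of the two-group
pre/post contrast.

### Predictors and standardization

Default predictor set: all six covariates (as pre-policy means) plus every
pre-policy year's outcome as a special predictor; both are configurable
(`covariates=`, `outcome_lags=`). Predictor rows are standardized
(center/scale across the `J+1` units) before optimization, because the
matching distance is scale-sensitive and the predictors mix persons,
currency and percentages — without standardization a population row in the
millions dominates every share. The standardization record is kept on the
fit and balance tables are always reported on the raw scale. A constant
row standardizes to zeros (scale forced to 1). Standardizing also makes
the match invariant to adding a constant to every unit's outcome, which is
what makes the counterfactual affine-equivariant.

### Solving the weight problem

For fixed `V` the inner problem is a convex QP on the probability simplex.
It is solved with SLSQP (analytic gradient, simplex bound and equality
constraints, two starts: uniform and the nearest-donor vertex), followed by
a KKT polish: an equality-constrained least-squares solve restricted to the
positive support, accepted only when feasible and objective-improving.
The polish brings interior/hull solutions to machine precision (the
brute-force grid tests and the noiseless recovery tests rely on this).
A solution is validated against `wⱼ ≥ −1e−8`, `|Σwⱼ − 1| ≤ 1e−8`; an
infeasible result raises rather than returning silently. Weights below
0.001 are *displayed* as "≈ 0" but stored at full precision.

### Choosing V

The importance weights are not identified by the matching problem itself;
the package follows the standard data-driven choice: `V` (on the
k-simplex) minimizes the pre-policy outcome MSPE of the synthetic unit
implied by `W(V)` — a nested, bilevel problem. The outer problem is solved
with SLSQP (numeric gradient) from a multistart of equal weights plus
`n_restarts` seeded Dirichlet draws; the equal-weights value is always
evaluated, so the result is never worse than equal importance. `k = 1`
short-circuits to `V = (1)`. If every start fails the estimator falls back
to equal importance with a warning. `v_mode="equal"` skips the nested
optimization entirely; it is the configuration used for the large
Monte-Carlo suites in the tests (hundreds to thousands of fits), where the
nested layer adds cost but no information about the properties under test —
the nested optimizer itself is verified against a dense 1-D grid at k = 2.

### Effects, fit quality, and the donor-level adjustment

`effect_summary` reports the signed mean post-policy gap, its absolute
value, and the relative effect |mean gap| / `Y₁,baseline` × 100 with the
baseline year defaulting to `T₀ − 1`. Machine outputs keep full precision;
the human-readable report rounds to one decimal.

Pre-policy MSPE above a threshold (`poor_fit_mspe`, default 25 pp²,
i.e. RMSE 5 pp) triggers a warning that no convex combination of donors
tracks the treated unit. The canonical cause is a persistent level offset:
a treated unit sitting ~10 pp below every donor is outside the donor hull
at every point. `adjust_donor_level(panel, offset)` subtracts `offset`
percentage points from every donor outcome in every year (treated unit and
covariates untouched), restoring overlap; the adjustment is recorded in
provenance metadata and surfaces in reports. The additive reading (10
percentage points, not a 10% rescale) is the default because the use case
is a treated unit *lower by a fixed number of points*, and an additive
shift aligns the levels exactly; a multiplicative mode exists behind
`mode="multiplicative"`. Internally the panel keeps its unadjusted base
outcomes plus cumulative adjustment state and rematerializes donor values,
so adjusting by δ and then by −δ restores the original panel bit-exactly —
naive subtract-then-add would not, in floating point.

## Placebo permutation inference

Treatment is reassigned to each donor in turn; the estimator is refit with
the identical specification, giving a placebo gap path per donor. The
genuinely treated unit is excluded from placebo donor pools by default (its
real post-policy response would contaminate placebo counterfactuals; a
flag restores it). Placebos with pre-policy MSPE strictly greater than
`ratio_threshold` × the treated unit's (default 5) are excluded: their
large gaps reflect lack of fit, not effects. The pseudo p-value is the
proportion of *retained* placebos whose |mean post-policy gap| is at least
the treated unit's — so `p × retained` is always an integer, and the
treated unit is not self-counted in the denominator. An alternative
extremeness statistic (post/pre MSPE ratio) is available via
`effect_statistic="mspe_ratio"`. A placebo fit that fails to converge is
flagged with its reason and excluded, never silently dropped.

## Difference-in-differences cross-check

OLS on unit-year rows with an intercept, treated-unit dummy, post-period
dummy, their interaction, and the covariates at raw yearly values; `β₃` is
the effect. The model deliberately carries no unit or year fixed effects
beyond the two dummies (that is the model being cross-validated); two-way
fixed effects are available behind `two_way_fe=True`. Standard errors are
classical by default — matching the single-error-term model as written —
with cluster-by-unit available via `se_mode="cluster"`; reported intervals
always state the mode. Rank deficiency (e.g. a covariate constant within
all groups) is detected before fitting and reported with the offending
column name rather than silently pseudo-inverted.

## The synthetic-data generator

`Y_jt = θ_t + μ_j + λ_t f_j + τ_t D_jt + δ·1[j=1] + ε_jt`: common year
shocks `θ_t` (level 48 pp, trend −0.5 pp/yr, shock sd 0.4), unit effects
`μ_j ~ N(0, 3²)`, a trending factor `λ_t` (−0.8 pp/yr, shock sd 0.5) with
loadings `f_j ~ N(1, 0.4²)`, treatment `D_jt = 1[j = 1, t ≥ T₀]` with a
constant or ramped profile `τ_t`, an optional persistent treated offset
`δ`, and `ε_jt ~ N(0, σ²)` with σ = 1 pp by default. Defaults: 13 units,
2008–2015, policy year 2013 (5 pre, 3 post), τ = −7.7 pp. An interactive
fixed-effects DGP, not a parallel-trends one, is the default because it is
the setting where the synthetic-control premise (time-varying unobserved
factors) is meaningful and where the DiD-vs-SCM contrast is informative;
`f_sd = 0` degenerates to exact parallel trends for the DiD recovery
tests. `treated_in_hull=True` draws the treated unit's `(f, μ)` as one
Dirichlet-weighted convex combination of the donors' — which makes the
treated outcome path an *exact* convex combination of donor paths at σ = 0,
the construction behind the machine-precision recovery tests.

The six covariates are affine in `(f_j, μ_j)` plus a linear time trend and
noise, calibrated to prefecture-scale magnitudes (population 3–8 M,
urbanization 50–70%, elderly share 18–28%, GDP per capita 40–80 k, life
expectancy 77–82 y, medical operation expenses 150–300 per capita); the
`covariate_noise` multiplier controls how informative they are about the
latent loadings (0 = exact affine functions, used by the moment-calibration
test). Outcomes leaving [0, 100] are clipped with a warning, never
silently. Canned scenarios: `outpatient-like` (treated comparable to
donors, τ = −7.7, σ = 0.8, in-hull), `inpatient-like` (δ = −10 pp with
σ_μ = 2 pp, so the treated unit sits ~5σ_μ below the pool and no synthetic
control is constructible before a +10 donor adjustment; τ = −3.2), and
`null` (τ = 0, exchangeable treated unit, for calibration).

What the generator does *not* emulate: serial correlation in ε, spillovers
from the treated unit to donors, staggered or partial adoption in donor
cities, measurement revisions, and covariates affected by treatment.
Passing tests therefore demonstrate correctness of the estimators under
the factor model, not robustness of the design to those threats on real
data.

## Numerical and testing choices

- Simplex feasibility tolerances: 1e−8 for `W`, 1e−10 for `V`; these are
  the contract, independent of solver defaults.
- The brute-force oracle for the weight QP enumerates the simplex grid at
  step 0.001 exhaustively for J ≤ 3; at J = 4 (~1.7 × 10⁸ points) it uses
  an exhaustive 0.005 grid plus exhaustive 0.001 refinement around the
  coarse optimum. The assertion is one-sided — the solver is never worse
  than the grid by more than 1e−6 — because a 0.001-resolution grid point
  can itself sit above the true optimum by more than 1e−6 in objective.
- Monte-Carlo suite sizes (100-seed recovery, 200-replicate rank
  calibration at 13 units, 60–100 DiD replicates) were chosen so the whole
  suite runs in about a minute on one CPU while keeping Monte-Carlo error
  far from the asserted bounds.
- Ties (several donors matching exactly): the solver returns one optimum;
  tests assert the objective value, not the weight vector.
- Determinism: all randomness flows through explicit seeds
  (`numpy.random.default_rng`); a fixed config yields byte-identical
  report bundles, asserted in the tests.

## Known limitations

- One treated unit only; no aggregation over multiple treated units.
- No augmented/penalized synthetic-control variants, no in-time placebo
  tests, no confidence intervals for the SCM effect beyond the placebo
  permutation logic — the reporting mirrors the comparative-case-study
  tradition.
- The nested V optimization is a non-convex bilevel problem; multistart
  SLSQP finds good local optima (verified against a dense grid at k = 2)
  but carries no global guarantee at larger k.
- The DiD p-values assume the model's error structure; with common year
  shocks the classical intervals are conservative for β₃ (the shocks
  cancel in the double difference but inflate the residual variance).
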