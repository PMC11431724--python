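# Methods

## Model and objective

For an outcome y and a covariate frame, the candidate design is
X = [A B C]: main effects A (continuous columns and one-hot dummies),
interactions B (products of 2..k+1 covariates with pairwise-distinct
sources; k = 1 by default, i.e. all pairwise products), and polynomials C
(powers 2..poly of continuous covariates; poly = 2 by default).  Dummies
from the same categorical are never multiplied (the product is identically
zero or duplicates a dummy), and 0/1 columns get no polynomial terms
(x² = x).  The fit minimizes

    (1/2n)‖y − β0 − Xβ‖² + λ Σ wⱼ|βⱼ|        (Gaussian)
    −(1/n) ℓ(y; β0 + Xβ) + λ Σ wⱼ|βⱼ|        (binomial log-likelihood)

with the intercept always unpenalized.

## Penalty weights (ranked sparsity)

Weights are `wⱼ = pⱼ^γ` where pⱼ is the size of the group term j belongs
to, computed on the candidate set that survives the variance filter.
Mains form one group; each interaction order forms one group; a
polynomial of order m uses the cumulative count of candidate terms of
polynomial order ≤ m, counting mains at order 1 (so with 4 mains and
quadratics the order-2 weight is √8).  γ = 0.5 by default; γ = 0 gives
all-unit weights, i.e. the plain lasso on the expanded design.

Why the square root: treating each group's total penalty mass as its
prior "evidence budget", equal budgets across groups require weights
proportional to the root of group size.  Descriptions of this scheme
sometimes print the weight as the group size itself; the calibration
argument, and the behavior of sparseR (the established R implementation
of ranked sparsity), correspond to the root, so the exponent is exposed
as `gamma` with default 0.5.
Group sizes are taken after filtering because the prior budget should
count terms that can actually enter the model.

## Preparation recipe

Fit on training data only, replayed anywhere (no test statistics are ever
used): (1) categorical levels below 10% frequency merge into "other"
("other_merged" on name collision); (2) one-hot coding against the most
frequent level; (3) term expansion; (4) variance filtering; (5)
standardization of every candidate column.

Derived columns are built from **centered** continuous parents (better
conditioning, less main/interaction collinearity) and **raw 0/1**
dummies, then each column is standardized.  Keeping dummy products on the
raw scale is deliberate: the near-zero-variance screen is a frequency
screen, and only the raw product shows an interaction's true
co-occurrence sparsity.  Building products from standardized dummies
would spread them over four moderate-frequency levels and the screen
could never fire — which would erase the documented failure/fix mechanism
on apnea-like data.  Penalty comparability across term types comes from
the final per-column standardization, not from scaling the parents.

The filter runs on the expanded design (that is what removes candidate
interactions wholesale on skewed categorical data): `zv` drops exactly
constant columns; `nzv` (default) additionally drops columns whose
most-frequent/second-most-frequent value ratio exceeds 19 (a 95/5 split)
and whose distinct-value percentage is below 10 — the conventional
thresholds of the recipe frameworks this mirrors, both exposed in
`RecipeConfig`.  Missing values are a hard error: silent imputation would
change the method.  Unseen categorical levels at prediction time fall to
the reference level.

## Solver

Cyclic coordinate descent over a 100-point log-spaced λ grid from
λ_max = maxⱼ |xⱼᵀ(y − ȳ)|/(n wⱼ) down to λ_max·10⁻³ (10⁻² when p ≥ n),
with warm starts.  Updates use a cached Gram matrix when p ≤ 1500 and
residual updates otherwise; full sweeps alternate with active-set
refinement; convergence is declared when the largest absolute coefficient
change in a sweep falls below `tol` (default 1e−8).  The binomial family
is solved by IRLS (working weights floored at 1e−5, probabilities clipped
at 1e−10 in deviance computations) with the weighted least-squares
subproblem solved by the same coordinate scheme.  Inner loops are
compiled with numba when available; the uncompiled Python is an exact
fallback.  `kkt_residuals` provides an optimality certificate (score
bounded by λwⱼ for inactive terms, equality with the subgradient for
active ones); converged fits certify below 1e−6 in the test suite.
Non-convergence at a grid point is flagged, not fatal.

## Cross-validation and selection

The λ grid is computed once on the full training set and held fixed
across 10 folds (stratified for binary outcomes; a class smaller than the
fold count relaxes stratification with a warning; a fold with a constant
training response is skipped with a warning).  Fold losses are RMSE
(Gaussian) or mean binomial deviance (binary — tuning on deviance, never
accuracy); the standard error is sd(fold losses)/√K.  `lambda_min` is the
grid minimizer, ties resolved toward larger λ; `lambda_1se` is the
largest λ whose mean loss is within one SE of the minimum.  Gaussian CV
also reports a pooled out-of-fold R² per λ (1 − SSE/SST on stacked
predictions).

## Evaluation protocol

Test evaluation uses the sum-of-squared-errors R² (can be negative) and
RMSE for continuous outcomes, rank-statistic AUC (midrank ties) for
binary.  The clamp max(R², 0) is applied only where downstream modeling
needs a common scale (meta-analysis, summaries), never inside tuning.
The split protocol sets aside round(0.2·n) observations, stratified for
binary targets, deterministic in the seed.

## Interpretation

The solver works on standardized columns; `coefficient_table` expands
every selected column symbolically into a polynomial in the raw encoded
features and accumulates onto canonical monomials (intercept, mains,
products, powers), so original-scale predictions from the table equal the
model's predictions to ~1e−10 (tested).  Zero coefficients are reported
as exact zeros.  `effect_profile` sweeps one covariate over 100 points of
its observed training range with all others pinned at the training median
(continuous) or mode (categorical) — reference choices made here, since
profiles require some anchoring — with one curve per moderator level
(range endpoints and midpoint for a continuous moderator), on the
probability scale for binomial models.

## Benchmark harness and meta-model

Dataset inclusion mirrors the benchmark protocol: binary or continuous
endpoints, n < 10,000, p ≤ 50, n·p < 100,000 cells, and
Friedman-simulation sets excluded (detected by registry naming
convention, shipped as editable configuration).  Every arm shares one
80/20 split per dataset; SRL/lasso arms tune by their own 10-fold CV;
black-box arms are thin adapters over scikit-learn/xgboost published
defaults (their internals are out of scope, and the harness runs with any
subset of arms, so the suite is fully testable offline with SRL + lasso).
"Within 5% of best" is relative — metric ≥ 0.95 × the dataset's best on a
higher-is-better scale (AUC, clamped test R²) — with ties crediting all
tied arms; the definition is config-exposed since absolute differences
are a defensible alternative.  Inference fits metric ~ algorithm with a
random intercept per dataset (statsmodels MixedLM, REML).  The contract
is the model structure; p-values are large-sample Wald tests rather than
Satterthwaite-adjusted small-sample tests, so with few datasets they run
slightly liberal.  A singular random-intercept variance triggers a
fixed-dataset-effects fallback with a warning.

## Synthetic generators

Each generator is a pure function of its seed and records its ground
truth.  What they emulate — and what they do not:

- `gen_parity` (n = 1124, 10 Bernoulli(½) bits, hidden 5-bit subset):
  the target is 1 iff the subset sum is even, so every feature and every
  low-order product is marginally independent of the target.  Chance AUC
  for the default SRL here is a structural certainty, not a measurement
  of real-data behavior.
- `gen_interaction_signal` (defaults n = 500, six standard-normal mains
  with coefficients (1, .5, .5, 0, 0, 0), one planted x1:x2 interaction
  of 1.0, noise sd 1): independent covariates and exact linearity, so
  recovery rates here are an upper bound on what correlated, messy data
  would give.
- `gen_zero_inflated_outcome` (defaults n = 475, zero mass 0.5,
  log-normal positive part, two 4-level factors with skewed margins
  (0.6, 0.1, 0.1, 0.2), +800 main bumps at the top level and +13,000 when
  both factors hit it, plus two skewed binary nuisance factors): matches
  the qualitative structure — point mass, right skew, rare huge
  two-factor interaction, and interaction dummies below the nzv
  frequency threshold while mains survive it.  The zero-mass proportion
  and scale are the package's own choices of a realistic regime; the raw
  values of the real apnea data are not reconstructed.
- `gen_high_order_polynomial` (n = 120, integer covariate 1–12, binary
  covariate, logit = 2.5·T₇(u) + 0.4·(official−½) with T₇ the degree-7
  Chebyshev polynomial on the scaled range): the oscillating shape has
  essentially no quadratic projection, forcing the default poly = 2 fit
  toward chance while poly = 7 can express it.
- `gen_benchmark_suite` / `gen_meta_table`: offline stand-ins for a
  benchmark registry; the meta-table plants algorithm offsets
  (0, −0.05, −0.15), dataset effects N(0.6, 0.15²) and noise N(0, 0.02²).

## Problem sizes and numerical choices

Stochastic checks use the generator defaults above with explicit
replicate counts: 100 seeds for interaction recovery, 20 seeds for
parity, 50 train/test splits for polynomial escalation, 100 replicate
meta-tables (the acceptance script uses 60/15/30/60 replicates of the
same conditions — sizes chosen as stable summaries of the same
distributions).  Solver comparisons against the sign-pattern QP oracle
use n = 20, p = 5, where 3⁵ enumeration is exact.  Tie-breaks: CV-loss
ties go to larger λ; dummy reference levels break frequency ties
lexicographically.  Degenerate inputs: constant targets are rejected; a
design emptied by filtering yields an intercept-only model; all-zero
penalty weights are rejected when a λ grid must be anchored.

## Known limitations

No imputation, no elastic-net/MCP/SCAD penalties, no outcome
normalization, no spline bases, no stacking.  Raw-power polynomial bases
of high order are ill-conditioned; coordinate descent still converges to
certificate accuracy but needs many sweeps (this is where the compiled
kernels matter).  Mixed-model p-values are asymptotic.  Hierarchy is not
enforced: an interaction can be selected without its mains (the penalty
weights discourage, not forbid, this).
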