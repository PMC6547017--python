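# Methods

## The question the simulations answer

When a large share of an outcome variable is missing, analysts often decide
between complete-case analysis (CCA) and multiple imputation (MI) by looking
at the *proportion* of missing data. That proportion, however, says nothing
about how much of the lost information can be recovered from other observed
variables. The fraction of missing information (FMI) — the share of a
pooled estimate's total variance attributable to between-imputation
variance — accounts for exactly that. This package reconstructs the
simulation design that contrasts the two quantities: cohorts with
controllable auxiliary information, outcome missingness at proportions from
1% to 90% under MCAR and MAR, MI under predictor sets of increasing
strength, and Monte-Carlo summaries of bias, precision and FMI.

## Population model

Each cohort is one draw of n iid rows from a 13-dimensional multivariate
normal: outcome `Y`, exposure `X`, auxiliaries `Z1..Z11`, all with mean 0
and SD 1. The correlation matrix has `Corr(Y,X) = 0.6`,
`Corr(Y, Z1) = Corr(Y, Z2) = 0.4`, `Corr(Y, Z3..Z7) = 0.2`,
`Corr(Y, Z8..Z11) = 0.1`, and *zero* correlation between any two non-outcome
variables. Orthogonal predictors make the squared coefficient of multiple
correlation with the outcome additive:

    R²_Y(S) = Σ_{v ∈ S} Corr(Y, v)²,

so the five canonical imputation models carry R²_Y = 0.36 `{X}`, 0.40
`{X,Z3}`, 0.52 `{X,Z1}`, 0.76 `{X,Z1..Z4}`, 0.92 `{X,Z1..Z11}`. The
structure is positive definite iff Σρ² < 1 (Schur complement on the Y row),
which the spec validator enforces with that closed form and the matrix
builder re-checks by eigendecomposition.

Sampling multiplies iid standard normals by the Cholesky factor of the
correlation matrix: the population covariance is matched exactly and a
single integer seed reproduces the cohort.

## Missingness mechanisms

Missingness is confined to `Y`.

* **MCAR** deletes the first `round(p·n)` rows (half-away-from-zero
  rounding; at the canonical grid `p·n` is integral). Because rows are iid,
  truncation is distributionally identical to random deletion and makes the
  achieved proportion exact.
* **MAR** masks row i with probability `expit(α + Z1ᵢ + Xᵢ)` (coefficients
  configurable, defaults 1 and 1). `α` is calibrated so the *expected*
  proportion equals the target: the linear predictor is N(0, c₁²+c₂²), so
  the expectation is a one-dimensional integral evaluated with an 80-node
  probabilists' Gauss–Hermite rule and inverted by Brent root finding
  (achieved−target < 1e-6; the quadrature error is orders of magnitude below
  that). `p = 0.5` returns α = 0 exactly by symmetry. No per-dataset
  renormalisation is applied: the achieved proportion is random per data
  set, as the mechanism implies.

Under this MAR model the complete-case slope of `Y ~ X` is biased because,
given X, selection still depends on Z1, which carries outcome information
(population CCA slopes ≈ 0.575 at p=0.1 down to ≈ 0.535 at p=0.6, rising
slightly again by p=0.9 as the selection saturates).

## Imputation

Proper (Bayesian) normal-linear-regression imputation under the standard
noninformative prior, the sampler behind `mi impute regress`-style
implementations:

1. OLS of observed `Y` on intercept + predictors over complete rows gives
   `β̂`, residual variance `s²` on ν = n_obs − k df, and `(X'X)⁻¹`.
2. Per imputation: `σ*² = s²·ν / χ²_ν`, `β* ~ N(β̂, σ*²(X'X)⁻¹)`, and each
   missing `Yᵢ` is filled with `β*·xᵢ + N(0, σ*²)`.

Draws are vectorised across all m imputations (one chi-square vector, one
(m × k) normal matrix, one matrix product for the fills), which is what
keeps full scenario grids tractable on one CPU. A residual sum of squares
below 1e-24·(‖y‖²+1) is snapped to exactly zero so that a noiseless outcome
yields a degenerate posterior (σ* = 0, β* = β̂) rather than rounding-noise
imputations.

The imputation model always contains the analysis-model covariate `X`
(enforced by the spec type); the five canonical predictor sets are
registered by label.

## Analysis, pooling and FMI

The analysis model is `yᵢ = β0 + β1 xᵢ + εᵢ` (truth: β0 = 0, β1 = 0.6,
residual variance 0.64), fitted by closed-form bivariate OLS — scalar for
single fits, vectorised over the m completed outcome vectors in the hot
path; the two routes are cross-checked against each other in the tests.

Rubin's rules: pooled estimate `q̄ = mean(q_j)`, within-variance
`W = mean(v_j)`, between-variance `B = var(q_j)` (divisor m−1), total
`T = W + (1+1/m)B`, relative increase `r = (1+1/m)B/W`, reference
`df = (m−1)(1+1/r)²`. FMI is reported in two forms:

* classic: `(1+1/m)B / T` — the large-m limit;
* df-adjusted: `(r + 2/(df+3)) / (r+1)` — the default in summaries, matching
  what pooled-inference routines in the major packages print; for m in the
  hundreds the two differ by < 0.01 (bounded by `2/(df+3)`).

Degenerate inputs: B = 0 gives FMI 0 with infinite df; W = 0 with B > 0 is
treated as r = +∞ (FMI 1, df = m−1). The large-sample reference df is used
throughout — no small-sample complete-data df correction — consistent with
n = 1000; at these sizes the corrected and uncorrected FMIs agree well
inside the reporting tolerance.

## Performance metrics

Across n_sim replicates, per coefficient: bias `mean(est) − truth` with MCSE
`sd/√n_sim`; empirical SE `sd(est)` (divisor n_sim−1) with normal-theory
MCSE `emp_se/√(2(n_sim−1))`; FMI median and IQR with type-7 (linear
interpolation) quantiles. MI-vs-CCA gains use the scenario-level summaries,
not per-replicate ratios:

    %SE reduction   = 100 (se_CCA − se_MI) / se_CCA
    %bias reduction = 100 (|bias_CCA| − |bias_MI|) / |bias_CCA|

The bias reduction is undefined at zero CCA bias (returned as NaN with a
warning) and can be negative when MI is more biased.

## Orchestration and reproducibility

A study is a (mechanism × proportion) grid of cells. Within a cell, each
replicate's masked data set is shared by the CCA fit and *every* imputation
model, so all comparisons are paired. Seeds are derived by index — a
`SeedSequence` over (master seed, mechanism, p, replicate, stage, model
label) — so results do not depend on execution order and any single archive
record can be recomputed in isolation from the seed ledger written
alongside it. A cell failure is logged and skipped without aborting the
grid.

## Problem sizes and Monte-Carlo error

Defaults reproduce the reference design: n = 1000 rows, n_sim = 1000
replicates, m = 1000 imputations (FMI is an unstable estimate at small m,
hence the large default). The shipped `configs/reduced.yaml` preset
(n_sim = 200, m = 200) is the desk-scale variant; its MCSEs are √5 ≈ 2.2×
larger. The test suite and the acceptance script run at n_sim = 500 and
m = 200 for FMI medians and empirical SEs, and raise n_sim to 2,000 for the
percentage-SE-reduction cells and 5,000–10,000 for the percentage-bias-
reduction cells: those are ratio statistics whose MC error is roughly
`100·(emp_se_MI/√n_sim)/|bias_CCA|` with denominators of only 0.03–0.05, so
they need proportionally more replicates to sit inside a ±3-point band.
At m = 200 the pooled estimate retains a known B/m variance share, inflating
its SE by `√(1 + r/m)`; the "no-auxiliary model gains nothing" check adds
exactly that analytic allowance instead of a widened tolerance.

## What the generator does and does not emulate

It emulates a prospective cohort with complete baseline covariates and a
partially missing continuous follow-up outcome, with auxiliary strength
dialled by marginal correlations. It does **not** emulate correlated
auxiliaries (real auxiliaries overlap, so their contributions would not add),
missingness in more than one variable, non-normal or binary outcomes, or
misspecified imputation models. Passing results therefore demonstrate the
behaviour of *correctly specified* MI under clean MAR/MCAR mechanisms —
they do not certify MI performance when the imputation model omits
missingness predictors (indeed the misspecified models 1–2 are shown to
track CCA bias) or when real-data complications apply.

## Known limitations

* Single analysis model (bivariate OLS); no multi-parameter Wald pooling.
* MNAR mechanisms are out of scope.
* The FMI df variant follows the pre-small-sample-correction reference df;
  packages applying the Barnard–Rubin correction will differ in the third
  decimal at these sizes.
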