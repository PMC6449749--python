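# Methods

## Problem

Sparse linear variable selection in genomic designs fails in two
characteristic ways. When two predictors are nearly identical (co-regulated
genes, technical duplicates), ℓ1 selection is *unstable*: it picks one of
the pair essentially at random. When a predictor is an exact linear
combination of others (X^k = aX^i + bX^j, e.g. a derived expression
signature over its constituent mutations), selection is *inconsistent*: the
irrepresentable condition

    |(X⁽²⁾)ᵀ X⁽¹⁾ ((X⁽¹⁾)ᵀX⁽¹⁾)⁻¹ sign(β⁽¹⁾)| < 1 − η   (elementwise)

fails, and ℓ1 selection provably prefers the combined variable. The
`diagnostics` module measures both hazards directly: a high-correlation
pair scan, and the violation rate of the condition over random active sets.

## Model

The Precision Lasso replaces the ℓ1 penalty with the trace norm of a
weighted coefficient diagonal:

    min_β  ½‖y − Xβ‖² + λ ‖ M(γ, μ) diag(β) ‖_*,
    M(γ, μ) = γ (XᵀX)^{1/2} + (1 − γ) (XᵀX + μI)^{−1/2}.

The covariance square root couples correlated columns so they enter or
leave the model together (stability); the smoothed inverse square root
up-weights columns that are linearly predictable from the rest — the
precision matrix's diagonal grows like 1/(1 − R²) — so redundant combined
variables are penalized harder (consistency). γ ∈ [0, 1] mixes the two
behaviours; μ > 0 makes the inverse well defined when XᵀX is singular
(p > n, or exactly dependent columns). For a binary response the quadratic
loss is replaced by the logistic negative log-likelihood.

Limiting cases, all covered by tests: orthonormal columns with γ = 1 give
exactly the Lasso; λ = 0 with full-rank X gives ordinary least squares;
exactly duplicated columns receive equal coefficients for any λ.

## Algorithm

The trace norm admits the variational bound
‖M diag(β)‖_* ≤ ½ tr(diag(β) M² diag(β) S⁻¹) + ½ tr(S) for any S ≻ 0, tight
at S = (diag(β) M² diag(β))^{1/2}. Freezing S at the current iterate makes
the penalty a quadratic form ½ βᵀ(M² ∘ S⁻¹)β (Hadamard product), so each
IRLS step solves (XᵀX + λ M² ∘ S⁻¹)β = Xᵀy — a majorize–minimize scheme.
For the logistic loss the inner step is one Newton step on the
quadratic-penalty majorizer with step halving, which preserves descent.

Numerical choices:

* **Smoothing.** S is built from (Q + ε²I)^{1/2}. The recorded objective is
  the ε-smoothed F_ε(β) = loss + λ tr((Q + ε²I)^{1/2}), which is provably
  non-increasing across iterations. ε follows a continuation schedule from
  1e−2 down to 1e−10 (times a scale factor 1 + tr(M²)/p), tightening each
  time the iterate stabilizes: a large initial ε prevents the first
  re-weighting from collapsing coordinates prematurely (β = 0 is a fixed
  point of the un-smoothed iteration), and the final ε leaves inactive
  coordinates orders of magnitude below the selection floor. Since F_ε is
  monotone in ε, the recorded trace stays non-increasing across schedule
  switches. Singular values of M diag(β) are computed directly by SVD
  rather than as eigenvalues of its Gram, because √ at zero amplifies
  eigensolver roundoff.
* **Initialization.** Ridge solution with penalty 1e−3·λ (logistic: one
  unpenalized working-response Newton step from β = 0). A warm start that
  is numerically zero is replaced by this initialization for the same
  fixed-point reason.
* **Degenerate systems.** Inner solves add a diagonal jitter of
  1e−9·mean(diag) when Cholesky fails, escalating tenfold, never crashing.
* **Convergence.** Relative change ‖β_{t+1} − β_t‖ / max(1, ‖β_t‖) below
  `tol` (default 1e−5) at the final ε, capped at `max_iter` (default 500).
  Coefficients below `zero_floor` (default 1e−6) are zeroed on output; the
  pre-floor vector is kept as `beta_raw` because its magnitude ordering of
  *all* variables is what selection-AUC scoring uses.
* **Intercept.** Never penalized: squared loss centers X and y and refits
  the intercept by means; the logistic Newton step carries it explicitly.

λ is tuned by the exactly-K rule: bisection in log λ (warm-started,
descending path first) until exactly K coefficients survive the zero
floor; if the count jumps over K, the smallest λ with at most K survivors
is kept and the selected set truncated to the top K by |β| (ties to the
lower index). Cross-validation is deliberately not the default: prediction
error does not track selection error in correlated designs.

## Hyperparameters

| Parameter | Default | Meaning |
|---|---|---|
| γ | estimated | covariance vs precision mixing, in [0, 1] |
| μ | 1e−2·mean(diag(XᵀX)), floored at 1e−8 | inverse smoothing; scale-equivariant, caps cond(XᵀX + μI) at 1 + 100p |
| λ | exactly-K rule | penalty weight |
| tol / max_iter / zero_floor | 1e−5 / 500 / 1e−6 | solver controls |

γ is estimated as the prevalence of correlated columns (any partner with
|r| ≥ 0.99) divided by the prevalence of linearly dependent columns,
clamped to [0, 1]. "Linearly dependent" has no canonical operational
definition; this package declares one: multiple R² ≥ 1 − 1e−6 when a
column is regressed on its min(p − 1, n − 2, 100) most correlated peers.
The probe is deterministic. On designs with only approximate correlation
the ratio clamps to 1 (pure covariance weighting); with no high
correlation at all it is 0 (pure precision weighting).

A scale caveat, documented rather than hidden: on unit-variance columns
XᵀX ≈ n·R, so the covariance term of M is O(√n) while the precision term is
O(1/√μ). Intermediate γ therefore behaves close to γ = 1 unless columns
are rescaled to unit norm; the penalty itself follows the model statement
above verbatim and does not renormalize.

## Synthetic data

`simulate` draws columns by a first-order auto-regressive scheme
X_j = c·X_{j−1} + √(1−c²)ε_j (marginally standard normal, adjacent
correlation c), then overwrites `n_dep` columns with exact combinations
a·X_i + b·X_j, a, b ∈ {±1, ±0.5}, of earlier non-dependent columns —
precisely the structure that breaks irrepresentability, and verified to do
so by a generator↔diagnostics cross test. Defaults: n = 250, p = 500,
k = 10 active columns (±effect_size, sampled outside the dependent set so
ground truth is well-posed), n_dep = 10, noise calibrated to a variance
signal-to-noise ratio of 2 when `noise_sd` is unset; c covers
{0, 0.5, 0.9, 0.99} in benchmarks with 0.9 as the single default. Binary
responses are Bernoulli through a logistic link of the same linear signal.

What the generator does **not** emulate: minor-allele-frequency structure
of genotypes, population stratification, heavy-tailed expression noise,
batch effects. Passing benchmarks on it therefore demonstrates behaviour
under correlation and exact dependence, not performance on any particular
real assay.

## Evaluation

Selection is scored against the simulated truth: ROC AUC of the |β|
ranking over all p variables (midrank ties; a selection metric, not a
prediction metric), plus fixed-K confusion counts with K = k. Benchmarks
report mean ± SD over replicates with seeds `seed + rep`; a method failing
on a replicate is recorded as missing and logged. The comparison Lasso arm
is scikit-learn's coordinate-descent path with the same exactly-K
convention (smallest α with at most K nonzeros).

Problem sizes in the test suite and acceptance script (10 replicates at
n = 250, p = 500; 50 random solver instances; 100 oracle designs) were
chosen as the smallest sizes at which the qualitative contrasts are stable
across seeds.

## Known limitations

* Each IRLS iteration costs one p×p SVD and one p×p solve; the practical
  ceiling on one core is a few thousand variables.
* The exactly-K search is approximate when the nonzero count jumps over K
  (the trace penalty moves correlated groups jointly); the truncation rule
  makes the output deterministic but the returned λ is then a bound, not
  an exact root.
* With γ = 0 and p ≫ n the penalty is only weakly sparsifying; very large
  λ values are needed for small K and the fitted magnitudes act more like
  a ranking than a hard selection.
* The γ estimate is a heuristic ratio of prevalences; it saturates at the
  extremes on purely auto-regressive designs.
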