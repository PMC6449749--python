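# precision-lasso

Sparse variable selection for designs with **highly correlated** and
**linearly dependent** predictors — the situation of gene-expression,
methylation and genotype matrices, where plain ℓ1 selection is *unstable*
(it picks one of a correlated group at random) and *inconsistent* (it
prefers a combined variable X^k = aX^i + bX^j over its constituents
whenever the irrepresentable condition fails).

The estimator is the Precision Lasso:

```
min_β  ½‖y − Xβ‖² + λ ‖ [ γ(XᵀX)^{1/2} + (1−γ)(XᵀX+μI)^{−1/2} ] diag(β) ‖_*
```

where ‖·‖_* is the trace norm (sum of singular values). The covariance
square root ties correlated columns together (stable selection); the
smoothed inverse — the precision-matrix side — up-weights columns that are
linearly predictable from the rest (consistent selection). γ ∈ [0, 1]
mixes the two and is estimated from the design by default; μ > 0 keeps the
inverse defined when p > n. A logistic-loss variant handles case-control
responses. The solver is iteratively re-weighted least squares on a
variational majorizer of the trace norm, with a provably non-increasing
objective trace. See `docs/methods.md` for the full model and numerical
choices.

The package also ships the supporting tooling: irrepresentability and
correlation diagnostics, an auto-regressive simulator with injected exact
linear dependencies, selection-quality scoring (variable-ranking AUC,
fixed-K confusion metrics), CSV and PLINK1 (.bed/.bim/.fam) input, and a
command-line interface.

## Worked example

```python
import numpy as np
from precision_lasso import (
    SimulationConfig, simulate_dataset, estimate_gamma,
    PenaltyConfig, SolverConfig, select_lambda_for_k,
    confusion_at_k, selection_auc,
)

cfg = SimulationConfig(n=250, p=500, k=10, ar_coef=0.9, n_dep=10, seed=1)
ds = simulate_dataset(cfg)           # X, y, true active set
X = ds.X.standardize()

gamma = estimate_gamma(X)
lam, res = select_lambda_for_k(
    X, ds.y,
    PenaltyConfig(gamma=gamma, mu="auto"),
    SolverConfig(max_iter=250, tol=1e-4),
    K=10,
)
m = confusion_at_k(res.selected, ds.true_active, X.p)
auc = selection_auc(np.abs(res.beta_raw), ds.true_active)
print(f"gamma={gamma:.2f} lambda={lam:.1f} selected={len(res.selected)} "
      f"tp={m.tp} recall={m.recall:.2f} auc={auc:.3f}")
```

Output:

```
gamma=0.00 lambda=1471.3 selected=10 tp=2 recall=0.20 auc=0.920
```

Read: at auto-regressive correlation 0.9 no column pair reaches the 0.99
correlation-scan threshold, so the γ estimate falls to 0 and the penalty
runs in pure precision-weighting mode; λ was bisected until exactly 10
variables survive. Exact-column hits (tp = 2) are scarce because each true
active is nearly interchangeable with its neighbours — which is precisely
why the variable-ranking AUC of 0.920 over all 500 columns, not the hit
count, is the headline selection metric.

From the shell, the same pipeline:

```bash
precision-lasso simulate --n 250 --p 500 --k 10 --ar-coef 0.99 --seed 1 --out sim/
precision-lasso fit --csv sim/X.csv --pheno sim/y.csv --select-k 10 --out coef.tsv
precision-lasso diagnose --csv sim/X.csv --k-grid 1,2,5,10 --out diag
```

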