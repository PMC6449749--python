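"""Design-matrix hazard diagnostics.

Quantifies the two failure modes of ℓ1 selection that the Precision Lasso
penalty targets:

* **instability** — highly correlated columns, found by
  :func:`correlation_scan`;
* **inconsistency** — failure of the irrepresentable condition

      |(X⁽²⁾)ᵀ X⁽¹⁾ ((X⁽¹⁾)ᵀ X⁽¹⁾)⁻¹ sign(β⁽¹⁾)| < 1 − η   (elementwise),

  where X⁽¹⁾ are the active columns and X⁽²⁾ the inactive ones, checked by
  :func:`check_irrepresentable` and summarized over random active sets by
  :func:`inconsistency_rate`.

:func:`estimate_gamma` turns the two prevalences into the mixing weight γ
used by the penalty: the prevalence of correlated columns divided by the
prevalence of linearly dependent columns, clamped to [0, 1].
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .design import DesignMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "IrrepresentabilityReport",
    "check_irrepresentable",
    "inconsistency_rate",
    "correlation_scan",
    "estimate_gamma",
    "write_pairs_tsv",
    "write_rate_table_tsv",
]

#: condition-number cutoff beyond which an active Gram is deemed collinear
_COLLINEAR_COND = 1e12


@dataclass
class IrrepresentabilityReport:
    active_idx: list[int]
    signs: np.ndarray
    lhs: np.ndarray            # |X2ᵀ X1 (X1ᵀX1)⁻¹ sign|, one entry per inactive column
    max_lhs: float
    eta: float
    holds: bool
    collinear: bool = False


def check_irrepresentable(
    X: DesignMatrix,
    active_idx,
    signs,
    eta: float = 1e-5,
) -> IrrepresentabilityReport:
    """Evaluate the irrepresentable condition for one active set.

    An exactly collinear active block (condition number of (X⁽¹⁾)ᵀX⁽¹⁾ above
    1e12) is reported with ``holds=False`` and ``collinear=True``: the
    inverse does not exist and the condition is deemed violated.
    """
    active_idx = [int(i) for i in active_idx]
    signs = np.asarray(signs, dtype=float).ravel()
    if len(active_idx) != signs.shape[0]:
        raise ValueError("active_idx and signs must have equal length")
    if not np.all(np.isin(signs, (-1.0, 1.0))):
        raise ValueError("signs must be ±1")
    if len(set(active_idx)) != len(active_idx):
        raise ValueError("active_idx must be unique")
    p = X.p
    inactive = np.setdiff1d(np.arange(p), active_idx)
    X1 = X.values[:, active_idx]
    X2 = X.values[:, inactive]
    C11 = X1.T @ X1
    cond = np.linalg.cond(C11)
    if not np.isfinite(cond) or cond > _COLLINEAR_COND:
        lhs = np.full(inactive.shape[0], np.nan)
        return IrrepresentabilityReport(
            active_idx, signs, lhs, float("inf"), float(eta),
            holds=False, collinear=True,
        )
    phi = np.linalg.solve(C11, signs)
    lhs = np.abs(X2.T @ (X1 @ phi))
    max_lhs = float(lhs.max()) if lhs.size else 0.0
    return IrrepresentabilityReport(
        active_idx, signs, lhs, max_lhs, float(eta),
        holds=bool(max_lhs < 1.0 - eta),
    )


def inconsistency_rate(
    X: DesignMatrix,
    K: int,
    n_reps: int = 100,
    eta: float = 1e-5,
    seed: int | None = 0,
) -> float:
    """Fraction of random size-K active sets that violate irrepresentability.

    Active sets are sampled uniformly without replacement; signs uniformly
    from {−1, +1}.
    """
    if not 1 <= K < X.p:
        raise ValueError(f"need 1 <= K < p, got K={K}, p={X.p}")
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_reps):
        active = rng.choice(X.p, size=K, replace=False)
        signs = rng.choice([-1.0, 1.0], size=K)
        if not check_irrepresentable(X, active, signs, eta).holds:
            violations += 1
    return violations / n_reps


def correlation_scan(X: DesignMatrix, threshold: float) -> list[tuple[int, int, float]]:
    """All unordered column pairs with |Pearson r| ≥ threshold.

    Returns (i, j, r) with i < j, sorted by descending |r|. Pairs involving
    a constant column (undefined correlation) are skipped.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X.values, rowvar=False)
    corr = np.atleast_2d(corr)
    corr = np.nan_to_num(corr, nan=0.0)
    iu, ju = np.triu_indices(X.p, k=1)
    mask = np.abs(corr[iu, ju]) >= threshold
    pairs = [
        (int(i), int(j), float(corr[i, j]))
        for i, j in zip(iu[mask], ju[mask])
    ]
    pairs.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    return pairs


def estimate_gamma(
    X: DesignMatrix,
    corr_threshold: float = 0.99,
    dep_threshold: float = 1.0 - 1e-6,
    max_regressors: int = 100,
) -> float:
    """Estimate the penalty mixing weight γ from the design.

    γ = clamp(prevalence_corr / prevalence_dep, 0, 1) where

    * prevalence_corr — fraction of columns with at least one partner at
      |r| ≥ ``corr_threshold``;
    * prevalence_dep — fraction of columns whose multiple R², regressed on
      up to ``max_regressors`` (capped at min(p−1, n−2)) other columns
      chosen by largest |r|, reaches ``dep_threshold``.

    The "linearly dependent" prevalence has no single canonical definition;
    the bounded-R² probe above is this package's documented convention. The
    result is deterministic for a given X.
    """
    if not (0.0 < corr_threshold <= 1.0 and 0.0 < dep_threshold <= 1.0):
        raise ValueError("thresholds must be in (0, 1]")
    n, p = X.n, X.p
    if p < 2:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.nan_to_num(np.corrcoef(X.values, rowvar=False), nan=0.0)
    np.fill_diagonal(corr, 0.0)
    abs_corr = np.abs(corr)
    prevalence_corr = float(np.mean(abs_corr.max(axis=1) >= corr_threshold))

    centered = X.values - X.values.mean(axis=0)
    sst = np.einsum("ij,ij->j", centered, centered)
    m = min(p - 1, n - 2, max_regressors)
    dep = 0
    for j in range(p):
        if sst[j] <= 0.0:
            continue  # constant column: no linear dependence to speak of
        order = np.argsort(-abs_corr[j])
        others = [int(i) for i in order if i != j][:m]
        Z = centered[:, others]
        coef, _, _, _ = np.linalg.lstsq(Z, centered[:, j], rcond=None)
        resid = centered[:, j] - Z @ coef
        r2 = 1.0 - float(resid @ resid) / float(sst[j])
        if r2 >= dep_threshold:
            dep += 1
    prevalence_dep = dep / p
    gamma = prevalence_corr / max(prevalence_dep, 1e-12)
    return float(np.clip(gamma, 0.0, 1.0))


def write_pairs_tsv(pairs, column_names, path) -> None:
    """Write a correlation-scan pair list as TSV (i, j, name_i, name_j, r)."""
    with open(path, "w") as fh:
        fh.write("i\tj\tname_i\tname_j\tr\n")
        for i, j, r in pairs:
            fh.write(f"{i}\t{j}\t{column_names[i]}\t{column_names[j]}\t{r:.6g}\n")


def write_rate_table_tsv(rates: dict[int, float], path) -> None:
    """Write an inconsistency rate-by-K table as TSV (K, rate)."""
    with open(path, "w") as fh:
        fh.write("K\tinconsistency_rate\n")
        for k in sorted(rates):
            fh.write(f"{k}\t{rates[k]:.6g}\n")
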