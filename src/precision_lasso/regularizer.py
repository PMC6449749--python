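"""The Precision Lasso penalty.

The penalty applied to a coefficient vector β is the trace norm (sum of
singular values) of ``M(γ, μ) diag(β)`` where

    M(γ, μ) = γ (XᵀX)^{1/2} + (1 - γ) (XᵀX + μI)^{-1/2}.

The covariance square root spreads weight across correlated columns (stable
selection); the smoothed inverse square root up-weights columns that are
linearly dependent on others, via the precision matrix (consistent
selection). γ ∈ [0, 1] mixes the two; μ > 0 keeps the inverse well defined
when XᵀX is singular (p > n or exactly dependent columns).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .design import DesignMatrix

__all__ = [
    "PenaltyConfig",
    "PenaltyWeightMatrix",
    "sym_sqrt",
    "smoothed_inv_sqrt",
    "select_mu",
    "build_penalty_weight",
    "trace_norm",
    "penalty_value",
]

#: eigenvalues of a PSD matrix below this are treated as exact zeros
EIG_FLOOR = 1e-10


@dataclass
class PenaltyConfig:
    """Hyperparameters of the penalty.

    gamma
        Mixing weight in [0, 1]; None means "estimate from the design"
        (see :func:`precision_lasso.diagnostics.estimate_gamma`).
    mu
        Smoothing for the inverse square root; ``"auto"`` resolves via
        :func:`select_mu`.
    lam
        Overall regularization weight λ ≥ 0.
    """

    gamma: float | None = None
    mu: float | str = "auto"
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma is not None and not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not (self.mu == "auto" or (np.isreal(self.mu) and self.mu > 0)):
            raise ValueError(f"mu must be positive or 'auto', got {self.mu!r}")
        if self.lam < 0:
            raise ValueError(f"lam must be nonnegative, got {self.lam}")


@dataclass
class PenaltyWeightMatrix:
    """The resolved p-by-p weighting matrix M(γ, μ), symmetric PSD."""

    matrix: np.ndarray
    gamma_used: float
    mu_used: float


def _check_symmetric(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {A.shape}")
    asym = float(np.max(np.abs(A - A.T))) if A.size else 0.0
    tol = 1e-8 * (1.0 + float(np.max(np.abs(A))) if A.size else 1.0)
    if asym > tol:
        raise ValueError(
            f"matrix is not symmetric: max |A - Aᵀ| = {asym:.3e} exceeds {tol:.3e}"
        )
    return 0.5 * (A + A.T)


def sym_sqrt(A: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition.

    Eigenvalues below ``EIG_FLOOR`` are clipped to zero, which keeps the
    result well defined for rank-deficient Gram matrices (p > n).
    """
    As = _check_symmetric(A)
    w, V = scipy.linalg.eigh(As)
    w = np.where(w < EIG_FLOOR, 0.0, w)
    B = (V * np.sqrt(w)) @ V.T
    return 0.5 * (B + B.T)


def smoothed_inv_sqrt(A: np.ndarray, mu: float) -> np.ndarray:
    """Return (A + μI)^{-1/2} for symmetric PSD A and μ > 0."""
    if not mu > 0:
        raise ValueError(f"mu must be positive, got {mu}")
    As = _check_symmetric(A)
    w, V = scipy.linalg.eigh(As)
    w = np.clip(w, 0.0, None) + mu
    C = (V / np.sqrt(w)) @ V.T
    return 0.5 * (C + C.T)


def select_mu(X: DesignMatrix, delta: float = 1e-2, floor: float = 1e-8) -> float:
    """Choose the inverse-smoothing μ for a design.

    Rule: ``μ = max(floor, delta * mean(diag(XᵀX)))``. It is
    scale-equivariant (scaling X by c scales μ by c²) and guarantees
    XᵀX + μI is invertible with condition number at most ``1 + p/delta``.
    """
    d = np.einsum("ij,ij->j", X.values, X.values)
    return max(floor, delta * float(d.mean()))


def resolve_mu(X: DesignMatrix, cfg: PenaltyConfig) -> float:
    return select_mu(X) if cfg.mu == "auto" else float(cfg.mu)


def build_penalty_weight(X: DesignMatrix, cfg: PenaltyConfig) -> PenaltyWeightMatrix:
    """Assemble M(γ, μ) = γ(XᵀX)^{1/2} + (1-γ)(XᵀX + μI)^{-1/2}."""
    if cfg.gamma is None:
        raise ValueError("gamma must be resolved to a number before building M")
    mu = resolve_mu(X, cfg)
    A = X.gram()
    M = cfg.gamma * sym_sqrt(A) + (1.0 - cfg.gamma) * smoothed_inv_sqrt(A, mu)
    return PenaltyWeightMatrix(matrix=M, gamma_used=float(cfg.gamma), mu_used=mu)


def trace_norm(A: np.ndarray) -> float:
    """Sum of singular values of A (the nuclear norm)."""
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("trace_norm requires finite entries")
    return float(np.sum(scipy.linalg.svdvals(A)))


def penalty_value(X: DesignMatrix, beta: np.ndarray, cfg: PenaltyConfig) -> float:
    """Evaluate the penalty ‖M(γ, μ) diag(β)‖_* for a coefficient vector."""
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != X.p:
        raise ValueError(f"beta has length {beta.shape[0]}, expected p = {X.p}")
    M = build_penalty_weight(X, cfg).matrix
    return trace_norm(M * beta[np.newaxis, :])
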