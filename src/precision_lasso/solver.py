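"""Iteratively re-weighted least squares for the Precision Lasso objective.

The squared-loss objective is

    F(β) = ½‖y − Xβ‖² + λ ‖M diag(β)‖_*,   M = γ(XᵀX)^{1/2} + (1−γ)(XᵀX+μI)^{−1/2},

with the logistic negative log-likelihood replacing the quadratic loss for
binary responses. Writing G = M² and Q(β) = diag(β) G diag(β), the trace
norm admits the variational upper bound

    ‖M diag(β)‖_* ≤ ½ tr(Q(β) S⁻¹) + ½ tr(S)      for every S ≻ 0,

with equality at S = Q(β)^{1/2}. Freezing S at the current iterate turns the
penalty into the quadratic form ½ βᵀ (G ∘ S⁻¹) β (∘ = Hadamard product), so
each iteration solves a weighted ridge system — a majorize–minimize scheme
whose ε-smoothed objective

    F_ε(β) = loss(β) + λ tr((Q(β) + ε²I)^{1/2})

decreases monotonically. ``objective_trace`` records F_ε per iteration.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
from scipy.special import expit

from .design import DesignMatrix
from .regularizer import EIG_FLOOR, PenaltyConfig, resolve_mu, sym_sqrt, smoothed_inv_sqrt, trace_norm

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "FitResult",
    "surrogate_objective",
    "fit",
    "fit_logistic",
    "select_lambda_for_k",
]


@dataclass
class SolverConfig:
    """Convergence controls for the IRLS solver."""

    max_iter: int = 500
    tol: float = 1e-5
    zero_floor: float = 1e-6
    loss: str = "squared"          # "squared" or "logistic"
    seed: int | None = None
    fit_intercept: bool = True

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if not self.zero_floor > 0:
            raise ValueError("zero_floor must be positive")
        if self.loss not in ("squared", "logistic"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class FitResult:
    """Solution of one Precision Lasso fit."""

    beta: np.ndarray
    intercept: float
    objective_trace: list[float]
    n_iter: int
    converged: bool
    selected: list[int] = field(default_factory=list)
    lam: float = 0.0
    gamma: float = 0.5
    mu: float = 0.0
    #: coefficients before the zero-floor cleanup; their magnitudes give a
    #: full ranking of all variables (useful for selection-AUC scoring)
    beta_raw: np.ndarray | None = None


def _resolve_gamma(X: DesignMatrix, pcfg: PenaltyConfig) -> float:
    if pcfg.gamma is not None:
        return float(pcfg.gamma)
    from .diagnostics import estimate_gamma  # local import avoids a cycle

    gamma = estimate_gamma(X)
    logger.info("estimated gamma = %.4f from the design", gamma)
    return gamma


def _penalty_factors(A: np.ndarray, gamma: float, mu: float):
    """(M, G=M²) from one eigendecomposition of A = XᵀX."""
    w, V = scipy.linalg.eigh(0.5 * (A + A.T))
    w = np.clip(w, 0.0, None)
    ws = np.where(w < EIG_FLOOR, 0.0, w)
    m = gamma * np.sqrt(ws) + (1.0 - gamma) / np.sqrt(w + mu)
    return (V * m) @ V.T, (V * (m * m)) @ V.T


def _solve_spd(H: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve Hx = b for (nominally) SPD H, recovering from rank deficiency
    by adding a diagonal jitter of 1e-9·mean(diag(H)), escalated tenfold on
    repeated failure."""
    jitter = 1e-9 * max(float(np.mean(np.diag(H))), 1e-30)
    for attempt in range(8):
        Ht = H if attempt == 0 else H + (jitter * 10.0 ** (attempt - 1)) * np.eye(H.shape[0])
        try:
            c, low = scipy.linalg.cho_factor(Ht, check_finite=False)
            return scipy.linalg.cho_solve((c, low), b, check_finite=False)
        except scipy.linalg.LinAlgError:
            continue
    return np.linalg.lstsq(H, b, rcond=None)[0]


def _weight_and_pen(beta: np.ndarray, M: np.ndarray, G: np.ndarray, eps: float):
    """Return (W, pen) for the variational majorizer at β:
    W = G ∘ S⁻¹ with S = (Q + ε²I)^{1/2}, Q = diag(β) G diag(β), and
    pen = tr(S) = Σ_i sqrt(σ_i² + ε²).

    S is assembled from the singular values σ of B = M diag(β) (Q = BᵀB),
    which are far better conditioned near zero than Q's eigenvalues.
    """
    B = M * beta[np.newaxis, :]
    _, sigma, Vt = scipy.linalg.svd(B, full_matrices=False)
    s = np.sqrt(sigma * sigma + eps * eps)
    Sinv = (Vt.T / s) @ Vt
    pen = float(np.sum(s))
    return G * Sinv, pen


def _floored_inverse(beta: np.ndarray, zero_floor: float) -> np.ndarray:
    """1/β with |β| floored at zero_floor (sign of 0 taken as +)."""
    sign = np.where(beta >= 0, 1.0, -1.0)
    mag = np.maximum(np.abs(beta), zero_floor)
    return 1.0 / (sign * mag)


def surrogate_objective(
    X: DesignMatrix,
    y: np.ndarray,
    beta: np.ndarray,
    cfg: PenaltyConfig,
    zero_floor: float = 1e-6,
) -> float:
    """The three-term surrogate upper bound of the penalized objective:

        ‖y − Xβ‖² + γ ‖[(X diag(β))ᵀ(X diag(β))]^{1/2}‖_*
                  + (1−γ) ‖[(X diag(β⁻¹))ᵀ(X diag(β⁻¹)) + μI]^{−1/2}‖_*

    Entries of β below ``zero_floor`` in magnitude are floored (at their
    sign) before inversion in the third term.
    """
    y = np.asarray(y, dtype=float).ravel()
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != X.p or y.shape[0] != X.n:
        raise ValueError("inconsistent shapes for X, y, beta")
    gamma = _resolve_gamma(X, cfg)
    mu = resolve_mu(X, cfg)
    r = y - X.values @ beta
    term_loss = float(r @ r)
    XB = X.values * beta[np.newaxis, :]
    term_cov = trace_norm(sym_sqrt(XB.T @ XB))
    XBi = X.values * _floored_inverse(beta, zero_floor)[np.newaxis, :]
    term_prec = trace_norm(smoothed_inv_sqrt(XBi.T @ XBi, mu))
    for name, val in (("loss", term_loss), ("covariance", term_cov), ("precision", term_prec)):
        if not np.isfinite(val):
            raise FloatingPointError(f"surrogate term '{name}' is non-finite")
    return term_loss + gamma * term_cov + (1.0 - gamma) * term_prec


def _selected(beta: np.ndarray, zero_floor: float) -> list[int]:
    nz = np.flatnonzero(np.abs(beta) > zero_floor)
    order = np.argsort(-np.abs(beta[nz]), kind="stable")
    return [int(i) for i in nz[order]]


def fit(
    X: DesignMatrix,
    y: np.ndarray,
    pcfg: PenaltyConfig | None = None,
    scfg: SolverConfig | None = None,
    beta0: np.ndarray | None = None,
) -> FitResult:
    """Minimize the Precision Lasso objective by IRLS.

    ``pcfg.gamma=None`` resolves γ from the design; ``pcfg.mu="auto"``
    resolves μ by the scale-equivariant default rule. A warm start may be
    supplied via ``beta0``. Coefficients with |βⱼ| below
    ``scfg.zero_floor`` are set to exactly 0 on output.
    """
    pcfg = pcfg or PenaltyConfig()
    scfg = scfg or SolverConfig()
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != X.n:
        raise ValueError(f"y has length {y.shape[0]}, expected n = {X.n}")
    if scfg.loss == "logistic":
        return _fit_logistic(X, y, pcfg, scfg, beta0)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    return _fit_squared(X, y, pcfg, scfg, beta0)


def _fit_squared(X, y, pcfg, scfg, beta0):
    gamma = _resolve_gamma(X, pcfg)
    mu = resolve_mu(X, pcfg)
    lam = float(pcfg.lam)
    Xv = X.values
    if scfg.fit_intercept:
        xm = Xv.mean(axis=0)
        ym = float(y.mean())
        Xc = Xv - xm
        yc = y - ym
    else:
        xm = np.zeros(X.p)
        ym = 0.0
        Xc, yc = Xv, y
    A = Xc.T @ Xc
    Xty = Xc.T @ yc

    if lam == 0.0:
        beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        r = yc - Xc @ beta
        trace = [0.5 * float(r @ r)]
        beta_raw = beta.copy()
        beta = np.where(np.abs(beta) <= scfg.zero_floor, 0.0, beta)
        return FitResult(
            beta=beta,
            intercept=ym - float(xm @ beta),
            objective_trace=trace,
            n_iter=1,
            converged=True,
            selected=_selected(beta, scfg.zero_floor),
            lam=lam, gamma=gamma, mu=mu, beta_raw=beta_raw,
        )

    M, G = _penalty_factors(A, gamma, mu)
    # smoothing continuation: start coarse so early re-weighting cannot
    # collapse coordinates prematurely, finish far below zero_floor so
    # inactive coordinates settle well under the selection threshold
    eps_scale = 1.0 + float(np.trace(G)) / X.p
    eps0 = 1e-2 * eps_scale
    eps_final = 1e-10 * eps_scale

    beta = None
    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).ravel().copy()
        if float(np.linalg.norm(beta)) < scfg.zero_floor:
            beta = None  # an all-zero start is a fixed point of the re-weighting
    if beta is None:
        # ridge start: a well-defined nonzero point for the re-weighting
        beta = _solve_spd(A + (1e-3 * lam) * np.eye(X.p), Xty)

    def loss(b):
        r = yc - Xc @ b
        return 0.5 * float(r @ r)

    eps = eps0
    W, pen = _weight_and_pen(beta, M, G, eps)
    trace = [loss(beta) + lam * pen]
    converged = False
    n_iter = 0
    for n_iter in range(1, scfg.max_iter + 1):
        beta_new = _solve_spd(A + lam * W, Xty)
        delta = float(np.linalg.norm(beta_new - beta)) / max(1.0, float(np.linalg.norm(beta)))
        beta = beta_new
        if delta < scfg.tol:
            if eps <= eps_final:
                W, pen = _weight_and_pen(beta, M, G, eps)
                trace.append(loss(beta) + lam * pen)
                converged = True
                break
            eps = max(1e-2 * eps, eps_final)  # tighten and keep iterating
        W, pen = _weight_and_pen(beta, M, G, eps)
        trace.append(loss(beta) + lam * pen)
    if not converged:
        logger.warning("IRLS did not converge in %d iterations", scfg.max_iter)

    beta_raw = beta.copy()
    beta = np.where(np.abs(beta) <= scfg.zero_floor, 0.0, beta)
    return FitResult(
        beta=beta,
        intercept=ym - float(xm @ beta),
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
        selected=_selected(beta, scfg.zero_floor),
        lam=lam, gamma=gamma, mu=mu, beta_raw=beta_raw,
    )


def _nll(z: np.ndarray, y: np.ndarray) -> float:
    # sum log(1 + e^z) - y z, numerically stable
    return float(np.sum(np.logaddexp(0.0, z) - y * z))


def fit_logistic(
    X: DesignMatrix,
    y: np.ndarray,
    pcfg: PenaltyConfig | None = None,
    scfg: SolverConfig | None = None,
    beta0: np.ndarray | None = None,
) -> FitResult:
    """Penalized logistic regression: negative log-likelihood + λ‖M diag(β)‖_*."""
    scfg = replace(scfg or SolverConfig(), loss="logistic")
    return fit(X, y, pcfg, scfg, beta0)


def _fit_logistic(X, y, pcfg, scfg, beta0):
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("logistic loss requires y in {0, 1}")
    if uniq.shape[0] < 2:
        raise ValueError("logistic loss requires both classes present")
    gamma = _resolve_gamma(X, pcfg)
    mu = resolve_mu(X, pcfg)
    lam = float(pcfg.lam)
    Xv = X.values
    n, p = X.n, X.p
    A = Xv.T @ Xv
    if lam > 0:
        M, G = _penalty_factors(A, gamma, mu)
    else:
        M = G = np.zeros((p, p))
    eps_scale = 1.0 + (float(np.trace(G)) / p if lam > 0 else 0.0)
    eps0 = 1e-2 * eps_scale
    eps_final = 1e-10 * eps_scale

    use_intercept = scfg.fit_intercept
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    b0 = float(np.log(ybar / (1.0 - ybar))) if use_intercept else 0.0
    beta = None
    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).ravel().copy()
        if float(np.linalg.norm(beta)) < scfg.zero_floor:
            beta = None
    if beta is None:
        # one unpenalized working-response Newton step from beta = 0
        pi = expit(np.full(n, b0))
        lam_w = np.maximum(pi * (1.0 - pi), 1e-10)
        H0 = (Xv * lam_w[:, None]).T @ Xv
        beta = _solve_spd(H0, Xv.T @ (y - pi))

    use_intercept = scfg.fit_intercept

    def nll(b, c):
        return _nll(c + Xv @ b, y)

    eps = eps0
    W, pen = _weight_and_pen(beta, M, G, eps) if lam > 0 else (np.zeros((p, p)), 0.0)
    trace = [nll(beta, b0) + lam * pen]
    converged = False
    n_iter = 0
    for n_iter in range(1, scfg.max_iter + 1):
        z = b0 + Xv @ beta
        pi = expit(z)
        lam_w = np.maximum(pi * (1.0 - pi), 1e-10)
        g_beta = Xv.T @ (pi - y) + lam * (W @ beta)
        H = (Xv * lam_w[:, None]).T @ Xv + lam * W
        if use_intercept:
            g0 = float(np.sum(pi - y))
            h_cross = Xv.T @ lam_w
            h00 = float(np.sum(lam_w))
            Haug = np.empty((p + 1, p + 1))
            Haug[:p, :p] = H
            Haug[:p, p] = h_cross
            Haug[p, :p] = h_cross
            Haug[p, p] = h00
            d = _solve_spd(Haug, np.concatenate([g_beta, [g0]]))
            d_beta, d0 = d[:p], float(d[p])
        else:
            d_beta, d0 = _solve_spd(H, g_beta), 0.0

        # step-halving line search on the quadratic-penalty majorizer
        g_cur = nll(beta, b0) + 0.5 * lam * float(beta @ (W @ beta))
        step = 1.0
        beta_new, b0_new = beta, b0
        for _ in range(40):
            cand_beta = beta - step * d_beta
            cand_b0 = b0 - step * d0
            g_cand = nll(cand_beta, cand_b0) + 0.5 * lam * float(cand_beta @ (W @ cand_beta))
            if g_cand <= g_cur + 1e-12:
                beta_new, b0_new = cand_beta, cand_b0
                break
            step *= 0.5

        delta = float(np.linalg.norm(beta_new - beta)) / max(1.0, float(np.linalg.norm(beta)))
        beta, b0 = beta_new, b0_new
        if delta < scfg.tol:
            if eps <= eps_final or lam == 0:
                if lam > 0:
                    W, pen = _weight_and_pen(beta, M, G, eps)
                trace.append(nll(beta, b0) + lam * pen)
                converged = True
                break
            eps = max(1e-2 * eps, eps_final)
        if lam > 0:
            W, pen = _weight_and_pen(beta, M, G, eps)
        trace.append(nll(beta, b0) + lam * pen)
    if not converged:
        logger.warning("logistic IRLS did not converge in %d iterations", scfg.max_iter)

    beta_raw = beta.copy()
    beta = np.where(np.abs(beta) <= scfg.zero_floor, 0.0, beta)
    return FitResult(
        beta=beta,
        intercept=b0 if use_intercept else 0.0,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
        selected=_selected(beta, scfg.zero_floor),
        lam=lam, gamma=gamma, mu=mu, beta_raw=beta_raw,
    )


def select_lambda_for_k(
    X: DesignMatrix,
    y: np.ndarray,
    pcfg: PenaltyConfig | None = None,
    scfg: SolverConfig | None = None,
    K: int = 1,
    max_fits: int = 40,
) -> tuple[float, FitResult]:
    """Bisection over log λ until the fit retains exactly K coefficients.

    If exact K is unattainable within the fit budget, returns the smallest
    evaluated λ giving at most K nonzeros, with the selected set truncated
    to the top K by |β| (ties broken toward the lower column index).
    """
    pcfg = pcfg or PenaltyConfig()
    scfg = scfg or SolverConfig()
    if not 1 <= K <= X.p:
        raise ValueError(f"need 1 <= K <= p, got K={K}, p={X.p}")
    y = np.asarray(y, dtype=float).ravel()
    # resolve data-dependent hyperparameters once so every fit shares them
    pcfg = replace(pcfg, gamma=_resolve_gamma(X, pcfg), mu=resolve_mu(X, pcfg))

    evaluated: dict[float, FitResult] = {}

    def run(lam: float, warm: np.ndarray | None) -> FitResult:
        res = fit(X, y, replace(pcfg, lam=lam), scfg, beta0=warm)
        evaluated[lam] = res
        return res

    def finish(lam: float, res: FitResult) -> tuple[float, FitResult]:
        if len(res.selected) > K:
            res = replace(res, selected=res.selected[:K])
        return lam, res

    if K == X.p:
        res = run(0.0, None)
        if len(res.selected) == K:
            return 0.0, res

    # lambda_max estimate from the per-coordinate penalty slope ||M e_j||
    yc = y - y.mean() if scfg.fit_intercept else y
    A = X.gram()
    _, G = _penalty_factors(A, float(pcfg.gamma), float(pcfg.mu))
    slope = np.sqrt(np.maximum(np.diag(G), 1e-12))
    lam = max(float(np.max(np.abs(X.values.T @ yc) / slope)), 1e-8)

    # descending warm-started path until the fit keeps >= K variables
    res = run(lam, None)
    fits = 1
    while len(res.selected) > K and fits < max_fits:  # lambda_max estimate too low
        lam *= 4.0
        res = run(lam, res.beta)
        fits += 1
    lam_hi, res_hi = lam, res       # count <= K
    lam_lo, res_lo = None, None     # count > K once found
    while fits < max_fits:
        if len(res.selected) == K:
            return finish(lam, res)
        if len(res.selected) > K:
            lam_lo, res_lo = lam, res
            break
        lam_hi, res_hi = lam, res
        lam *= 0.55
        res = run(lam, res.beta)
        fits += 1

    # bisect between the densest-feasible and first-infeasible lambda
    while lam_lo is not None and fits < max_fits and lam_hi / lam_lo > 1.0 + 1e-6:
        lam_mid = float(np.sqrt(lam_lo * lam_hi))
        res_mid = run(lam_mid, res_hi.beta)
        fits += 1
        if len(res_mid.selected) == K:
            return finish(lam_mid, res_mid)
        if len(res_mid.selected) > K:
            lam_lo, res_lo = lam_mid, res_mid
        else:
            lam_hi, res_hi = lam_mid, res_mid

    # exact K not reached: smallest evaluated lambda with <= K nonzeros
    feasible = [(lam, r) for lam, r in evaluated.items() if len(r.selected) <= K]
    if feasible:
        lam, res = min(feasible, key=lambda t: t[0])
    else:  # every fit kept > K: fall back to the sparsest one
        lam, res = max(evaluated.items(), key=lambda t: t[0])
    return finish(lam, res)
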