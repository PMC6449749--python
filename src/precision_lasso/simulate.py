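"""Synthetic designs with the correlation structure the penalty targets.

Columns follow a first-order auto-regressive scheme,

    X_1 ~ N(0, I),   X_j = c X_{j-1} + sqrt(1 - c²) ε_j,  ε_j ~ N(0, I),

so each column is marginally standard normal and adjacent columns have
population correlation c. A chosen number of columns is then overwritten by
exact two-parent linear combinations a·X_i + b·X_j (a, b ∈ {±1, ±0.5}),
reproducing the X^k = aX^i + cX^j pattern that breaks the irrepresentable
condition. Responses are sparse linear (continuous, Gaussian noise) or
Bernoulli through a logistic link.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DesignMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_design",
    "simulate_response",
    "simulate_dataset",
    "write_dataset_csv",
]


@dataclass
class SimulationConfig:
    """Knobs of the generator.

    noise_sd=None resolves, per dataset, to the value giving a
    variance signal-to-noise ratio of 2 for the continuous response.
    """

    n: int = 250
    p: int = 500
    k: int = 10
    ar_coef: float = 0.9
    n_dep: int = 10
    effect_size: float = 1.0
    noise_sd: float | None = None
    response: str = "continuous"   # "continuous" or "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n >= 2 and self.p >= 1):
            raise ValueError("need n >= 2 and p >= 1")
        if not 1 <= self.k <= self.p:
            raise ValueError("need 1 <= k <= p")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must be in [0, 1)")
        if self.n_dep < 0 or self.n_dep > self.p - self.k:
            raise ValueError("need 0 <= n_dep <= p - k")
        if self.n_dep > 0 and self.p < 3:
            raise ValueError("dependent columns need p >= 3")
        if self.noise_sd is not None and not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive (or None)")
        if self.response not in ("continuous", "binary"):
            raise ValueError(f"unknown response {self.response!r}")


@dataclass
class SyntheticDataset:
    X: DesignMatrix
    y: np.ndarray
    true_active: list[int]
    true_beta: np.ndarray
    config: SimulationConfig = field(repr=False)


def simulate_design(cfg: SimulationConfig) -> DesignMatrix:
    """Draw the AR design and inject exact linear dependencies.

    Indices of overwritten columns and their parents are recorded in
    ``meta["dependent_columns"]`` / ``meta["dependency_parents"]``.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n, p, c = cfg.n, cfg.p, cfg.ar_coef
    Z = rng.standard_normal((n, p))
    X = np.empty((n, p))
    X[:, 0] = Z[:, 0]
    s = np.sqrt(1.0 - c * c)
    for j in range(1, p):
        X[:, j] = c * X[:, j - 1] + s * Z[:, j]

    dep_cols: list[int] = []
    parents: dict[int, tuple[int, int, float, float]] = {}
    if cfg.n_dep > 0:
        targets = np.sort(rng.choice(np.arange(2, p), size=cfg.n_dep, replace=False))
        dep_set = set(int(t) for t in targets)
        coef_pool = np.array([1.0, -1.0, 0.5, -0.5])
        for t in targets:
            t = int(t)
            candidates = [i for i in range(t) if i not in dep_set]
            if len(candidates) < 2:   # cannot happen for p >= 4, defensive
                continue
            i, j = rng.choice(candidates, size=2, replace=False)
            a, b = rng.choice(coef_pool, size=2, replace=True)
            X[:, t] = a * X[:, int(i)] + b * X[:, int(j)]
            dep_cols.append(t)
            parents[t] = (int(i), int(j), float(a), float(b))

    return DesignMatrix(
        X,
        [f"x{j}" for j in range(p)],
        meta={"dependent_columns": dep_cols, "dependency_parents": parents},
    )


def simulate_response(X: DesignMatrix, cfg: SimulationConfig):
    """Draw (y, true_active, true_beta) for a simulated design.

    The k active columns are sampled uniformly among columns that were not
    overwritten as exact linear combinations, so the ground truth is
    well-posed. Active effects are ±effect_size with random signs.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    p = X.p
    dep = set(X.meta.get("dependent_columns", ()))
    candidates = np.array([j for j in range(p) if j not in dep])
    if candidates.shape[0] < cfg.k:
        raise ValueError("not enough independent columns for k active variables")
    true_active = np.sort(rng.choice(candidates, size=cfg.k, replace=False))
    true_beta = np.zeros(p)
    true_beta[true_active] = cfg.effect_size * rng.choice([-1.0, 1.0], size=cfg.k)

    signal = X.values @ true_beta
    if cfg.response == "continuous":
        if cfg.noise_sd is not None:
            sd = cfg.noise_sd
        else:
            sig_sd = float(signal.std())
            sd = sig_sd / np.sqrt(2.0) if sig_sd > 0 else 1.0  # variance SNR = 2
        y = signal + sd * rng.standard_normal(X.n)
    else:
        y = rng.binomial(1, expit(signal)).astype(float)
    return y, [int(j) for j in true_active], true_beta


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    X = simulate_design(cfg)
    y, true_active, true_beta = simulate_response(X, cfg)
    return SyntheticDataset(X=X, y=y, true_active=true_active,
                            true_beta=true_beta, config=cfg)


def write_dataset_csv(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write X.csv, y.csv and truth.tsv into ``outdir`` (CSV dialect of io)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = [f"s{i}" for i in range(ds.X.n)]
    x_path = outdir / "X.csv"
    y_path = outdir / "y.csv"
    t_path = outdir / "truth.tsv"
    pd.DataFrame(ds.X.values, index=ids, columns=ds.X.column_names).to_csv(
        x_path, float_format="%.17g", index_label="sample_id"
    )
    pd.DataFrame({"y": ds.y}, index=ids).to_csv(
        y_path, float_format="%.17g", index_label="sample_id"
    )
    with open(t_path, "w") as fh:
        fh.write("variable\ttrue_beta\tactive\n")
        for j, name in enumerate(ds.X.column_names):
            fh.write(f"{name}\t{ds.true_beta[j]:.17g}\t{int(j in set(ds.true_active))}\n")
    return {"X": x_path, "y": y_path, "truth": t_path}
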