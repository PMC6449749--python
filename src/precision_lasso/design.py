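"""Design-matrix container and column standardization."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["DesignMatrix"]


@dataclass
class DesignMatrix:
    """An n-by-p numeric predictor matrix with named columns.

    Parameters
    ----------
    values
        Samples in rows, variables in columns. Must be finite.
    column_names
        One identifier per column; auto-generated (``x0 .. x{p-1}``) when None.
    standardized
        True when columns are centered and non-constant columns have unit
        (population) variance. Set by :meth:`standardize`.
    meta
        Free-form provenance, e.g. indices of simulated dependent columns.
    """

    values: np.ndarray
    column_names: list[str] | None = None
    standardized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"design matrix must be 2-D, got shape {v.shape}")
        n, p = v.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 variable")
        if not np.all(np.isfinite(v)):
            bad = np.argwhere(~np.isfinite(v))
            raise ValueError(
                f"design matrix contains {len(bad)} non-finite entries; "
                f"first at (row, column) = {tuple(int(i) for i in bad[0])}"
            )
        if self.column_names is None:
            self.column_names = [f"x{j}" for j in range(p)]
        else:
            self.column_names = [str(c) for c in self.column_names]
        if len(self.column_names) != p:
            raise ValueError(
                f"{len(self.column_names)} column names for {p} columns"
            )
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, values, column_names=None, **kwargs) -> "DesignMatrix":
        return cls(np.asarray(values, dtype=float), column_names, **kwargs)

    def standardize(self) -> "DesignMatrix":
        """Center every column; scale non-constant columns to unit variance.

        Constant (zero-variance) columns are centered but left unscaled, with
        a logged warning, so behavior on degenerate input is deterministic.
        """
        if self.standardized:
            return self
        v = self.values
        centered = v - v.mean(axis=0)
        sd = centered.std(axis=0)
        const = sd < 1e-12
        if const.any():
            names = [self.column_names[j] for j in np.flatnonzero(const)[:5]]
            logger.warning(
                "%d constant column(s) left unscaled (e.g. %s)",
                int(const.sum()), names,
            )
        scale = np.where(const, 1.0, sd)
        return DesignMatrix(
            centered / scale,
            list(self.column_names),
            standardized=True,
            meta=dict(self.meta),
        )

    def gram(self) -> np.ndarray:
        """Return the p-by-p Gram matrix XᵀX."""
        return self.values.T @ self.values
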