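"""Spearman rank-correlation screening across the mother-infant indicators.

Spearman's rho is the Pearson correlation of average (mid) ranks — the
tie-correct estimator, which this dataset needs because most indicators are
categorical codes or small-integer scores.  For tie-free inputs it coincides
with the textbook 1 - 6*sum(d_i^2) / (n(n^2-1)) form.  Only coefficients are
reported (no p-values), matching how the screening is used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schema import DyadlinkError

logger = logging.getLogger(__name__)

__all__ = ["CorrelationMatrix", "spearman_rho", "correlation_matrix"]


class UndefinedCorrelationError(DyadlinkError):
    """Spearman's rho is undefined (n < 3 or a rank-constant argument)."""


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-correct Spearman rank correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise UndefinedCorrelationError(f"need n >= 3 observations, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input: rank variance is zero")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman matrix plus a |rho|-sorted pair listing."""

    variables: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        np.fill_diagonal(self.matrix, 1.0)

    @property
    def pairs(self) -> pd.DataFrame:
        """Off-diagonal pairs (var1, var2, rho), sorted by |rho| descending."""
        rows = []
        for i, a in enumerate(self.variables):
            for j in range(i + 1, len(self.variables)):
                rows.append((a, self.variables[j], self.matrix[i, j]))
        out = pd.DataFrame(rows, columns=["var1", "var2", "rho"])
        return out.reindex(
            out["rho"].abs().sort_values(ascending=False, kind="stable").index
        ).reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.variables, columns=self.variables)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def correlation_matrix(
    dataset: pd.DataFrame, variables: list[str] | tuple[str, ...] | None = None
) -> CorrelationMatrix:
    """Pairwise Spearman matrix over the given (ordered) variables.

    Constant columns yield NaN rows/columns (logged) rather than an error so
    a single degenerate indicator does not abort the screening.
    """
    if variables is None:
        variables = [c for c in dataset.columns if c != "dyad_id"]
    variables = tuple(variables)
    missing = [v for v in variables if v not in dataset.columns]
    if missing:
        raise KeyError(f"variable(s) not in dataset: {', '.join(missing)}")
    k = len(variables)
    mat = np.full((k, k), np.nan)
    constant = {v for v in variables if np.ptp(dataset[v].to_numpy(dtype=float)) == 0}
    if constant:
        logger.warning("constant column(s) have undefined correlations: %s", sorted(constant))
    for i in range(k):
        mat[i, i] = 1.0
        for j in range(i + 1, k):
            if variables[i] in constant or variables[j] in constant:
                continue
            rho = spearman_rho(
                dataset[variables[i]].to_numpy(dtype=float),
                dataset[variables[j]].to_numpy(dtype=float),
            )
            mat[i, j] = mat[j, i] = rho
    return CorrelationMatrix(variables=variables, matrix=mat)
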