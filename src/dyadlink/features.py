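"""Tree-based feature-importance scoring and top-k selection.

Importance magnitudes come from the impurity decrease of a seeded random
forest (they are nonnegative and sum to one); the displayed *sign* of each
feature is taken separately from the direction of its Spearman correlation
with the target.  Impurity importance cannot be negative, so magnitude and
direction are reported as two separate facts rather than a fabricated signed
importance.

A Spearman-based ranking is also exposed: for the wake-times target the
screening step selects by rank correlation rather than by the tree model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .correlation import UndefinedCorrelationError, spearman_rho
from .schema import ConfigError, DyadlinkError

__all__ = [
    "FeatureImportanceReport",
    "tree_importances",
    "select_features",
    "rank_by_spearman",
]


@dataclass
class FeatureImportanceReport:
    """Signed feature-importance display for one target variable."""

    target: str
    features: tuple[str, ...]
    magnitudes: np.ndarray        # nonnegative, sums to 1
    signs: np.ndarray             # -1 / 0 / +1 from Spearman direction
    ranking: tuple[str, ...]      # by magnitude desc, ties by column order

    @property
    def signed(self) -> np.ndarray:
        return self.magnitudes * self.signs

    def to_frame(self) -> pd.DataFrame:
        """Bar-chart-ready (feature, signed_importance) table in column order."""
        return pd.DataFrame(
            {"feature": self.features, "signed_importance": self.signed,
             "magnitude": self.magnitudes}
        )


def _is_classification(y: np.ndarray) -> bool:
    values = np.unique(y)
    return values.size <= 10 and np.allclose(values, np.round(values))


def tree_importances(
    X: pd.DataFrame,
    y,
    seed: int = 0,
    n_trees: int = 500,
    target_name: str | None = None,
) -> FeatureImportanceReport:
    """Impurity importances of a seeded forest, with Spearman-direction signs.

    Small-integer targets get a classification forest, continuous targets a
    regression forest.  Deterministic under a fixed seed.
    """
    if len(X) < 30:
        raise ConfigError(f"need at least 30 rows for stable importances, got {len(X)}")
    if X.shape[1] < 2:
        raise ConfigError("need at least 2 candidate features")
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise DyadlinkError("constant target: importances are undefined")
    cls = RandomForestClassifier if _is_classification(y) else RandomForestRegressor
    forest = cls(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(X.to_numpy(dtype=float), y.astype(int) if cls is RandomForestClassifier else y)

    magnitudes = forest.feature_importances_
    total = magnitudes.sum()
    magnitudes = magnitudes / total if total > 0 else np.full(X.shape[1], 1.0 / X.shape[1])

    signs = np.zeros(X.shape[1])
    for j, col in enumerate(X.columns):
        try:
            signs[j] = np.sign(spearman_rho(X[col].to_numpy(dtype=float), y))
        except UndefinedCorrelationError:
            signs[j] = 0.0

    order = sorted(range(X.shape[1]), key=lambda j: (-magnitudes[j], j))
    return FeatureImportanceReport(
        target=target_name or "target",
        features=tuple(X.columns),
        magnitudes=magnitudes,
        signs=signs,
        ranking=tuple(X.columns[j] for j in order),
    )


def select_features(report: FeatureImportanceReport, k: int = 4) -> list[str]:
    """Top-k features by importance magnitude (ties -> earlier canonical column)."""
    if not 1 <= k <= len(report.features):
        raise ConfigError(f"k must be in [1, {len(report.features)}], got {k}")
    return list(report.ranking[:k])


def rank_by_spearman(X: pd.DataFrame, y, k: int | None = None) -> list[str]:
    """Features ranked by |Spearman correlation| with the target.

    The alternative screening rule used for the wake-times target; undefined
    correlations rank last.  Returns the top-k when ``k`` is given, else the
    full ranking.
    """
    y = np.asarray(y, dtype=float)
    strengths = []
    for j, col in enumerate(X.columns):
        try:
            strengths.append((abs(spearman_rho(X[col].to_numpy(dtype=float), y)), -j))
        except UndefinedCorrelationError:
            strengths.append((-1.0, -j))
    order = sorted(range(X.shape[1]), key=lambda j: strengths[j], reverse=True)
    ranking = [X.columns[j] for j in order]
    if k is not None:
        if not 1 <= k <= len(ranking):
            raise ConfigError(f"k must be in [1, {len(ranking)}], got {k}")
        return ranking[:k]
    return ranking
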