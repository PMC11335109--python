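"""Dyad CSV I/O, outlier screening, and min-max normalization.

The canonical on-disk form is a UTF-8 comma-separated file with the fixed
header of :data:`dyadlink.schema.COLUMNS`.  Outlier removal applies explicit
per-variable interval rules (the screening criteria are configuration, not a
hidden heuristic); min-max normalization maps each indicator onto [0, 1] via
(x - min) / (max - min) with the fit-time extrema stored for reuse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    CATEGORICAL_LEVELS,
    COLUMNS,
    PLAUSIBILITY,
    ConfigError,
    SchemaError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OutlierRules",
    "NormalizationState",
    "read_dyads",
    "write_dyads",
    "remove_outliers",
    "fit_minmax",
    "apply_minmax",
]

_INT_COLUMNS = (
    "dyad_id", "marital_status", "education", "delivery_mode", "cbts", "epds",
    "hads", "behavior_class", "infant_gender", "wake_times", "sleep_mode",
)
_FLOAT_COLUMNS = ("maternal_age", "gestation_weeks", "infant_age", "sleep_time")


@dataclass(frozen=True)
class OutlierRules:
    """Per-variable screening rules: closed numeric intervals + allowed levels."""

    intervals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PLAUSIBILITY)
    )
    allowed_levels: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(CATEGORICAL_LEVELS)
    )

    def validate(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise ConfigError(f"interval for '{name}' has lower > upper")
        for name, levels in self.allowed_levels.items():
            if len(levels) == 0:
                raise ConfigError(f"allowed levels for '{name}' is empty")


def read_dyads(path: str | Path) -> pd.DataFrame:
    """Read a canonical dyad CSV into a typed table.

    Rows with missing required fields are dropped (logged with a count); a
    missing column or an unparseable cell raises :class:`SchemaError` naming
    the offender.  When the file lacks a ``dyad_id`` column, 1-based row
    numbers are used.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    required = [c for c in COLUMNS if c != "dyad_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "dyad_id" not in df.columns:
        df.insert(0, "dyad_id", np.arange(1, len(df) + 1).astype(str))

    incomplete = df[list(COLUMNS)].isna().any(axis=1)
    if incomplete.any():
        logger.info(
            "dropped %d row(s) with missing required fields (listwise deletion)",
            int(incomplete.sum()),
        )
        df = df.loc[~incomplete]

    out = pd.DataFrame(index=df.index)
    for col in COLUMNS:
        target = np.int64 if col in _INT_COLUMNS else float
        try:
            out[col] = df[col].astype(float).astype(target)
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad.index[0]) + 2  # header + 1-based
            raise SchemaError(
                f"unparseable value {bad.iloc[0]!r} in column '{col}' (file row {row})"
            ) from None
    return out.reset_index(drop=True)


def write_dyads(dataset: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical CSV dialect (UTF-8, comma-separated, fixed header)."""
    missing = [c for c in COLUMNS if c not in dataset.columns]
    if missing:
        raise SchemaError(f"dataset lacks column(s): {', '.join(missing)}")
    dataset[list(COLUMNS)].to_csv(path, index=False, encoding="utf-8")


def remove_outliers(
    dataset: pd.DataFrame, rules: OutlierRules | None = None
) -> tuple[pd.DataFrame, list[int]]:
    """Drop every record violating at least one rule; keep input order.

    Returns the surviving table and the exhaustive list of removed
    ``dyad_id`` values.  Idempotent: a second pass removes nothing.
    """
    rules = rules or OutlierRules()
    rules.validate()
    bad = np.zeros(len(dataset), dtype=bool)
    for name, (lo, hi) in rules.intervals.items():
        if name in dataset.columns:
            x = dataset[name].to_numpy(dtype=float)
            bad |= (x < lo) | (x > hi) | ~np.isfinite(x)
    for name, levels in rules.allowed_levels.items():
        if name in dataset.columns:
            bad |= ~dataset[name].isin(levels).to_numpy()
    removed = [int(i) for i in dataset.loc[bad, "dyad_id"]]
    if removed:
        logger.info("removed %d outlier record(s)", len(removed))
    return dataset.loc[~bad].reset_index(drop=True), removed


@dataclass(frozen=True)
class NormalizationState:
    """Fit-time per-column extrema of the min-max transform."""

    columns: tuple[str, ...]
    minima: np.ndarray
    maxima: np.ndarray

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of columns with max == min (mapped to 0 at apply time)."""
        return self.maxima == self.minima


def fit_minmax(matrix: pd.DataFrame | np.ndarray) -> NormalizationState:
    """Record column minima/maxima; degenerate (constant) columns are flagged."""
    if isinstance(matrix, pd.DataFrame):
        columns = tuple(matrix.columns)
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        columns = tuple(f"x{i}" for i in range(values.shape[1]))
    if not np.isfinite(values).all():
        raise ConfigError("min-max fit requires finite values")
    state = NormalizationState(columns, values.min(axis=0), values.max(axis=0))
    if state.degenerate.any():
        names = [c for c, d in zip(columns, state.degenerate) if d]
        logger.warning("degenerate (constant) column(s) in min-max fit: %s", names)
    return state


def apply_minmax(
    state: NormalizationState, matrix: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """(x - min) / (max - min) per column, clamped to [0, 1].

    Degenerate columns map to 0.  Values outside the fit-time range are
    clamped so downstream distance computations stay inside the unit cube.
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix[list(state.columns)].to_numpy(dtype=float)
    values = np.asarray(matrix, dtype=float)
    if values.shape[1] != len(state.columns):
        raise SchemaError(
            f"expected {len(state.columns)} column(s), got {values.shape[1]}"
        )
    span = np.where(state.degenerate, 1.0, state.maxima - state.minima)
    scaled = (values - state.minima) / span
    scaled[:, state.degenerate] = 0.0
    return np.clip(scaled, 0.0, 1.0)
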