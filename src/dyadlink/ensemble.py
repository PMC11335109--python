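"""MAE-gated ensemble of MLP and random-forest base learners.

The infant behavior class (quiet/moderate/contradictory, coded 0/1/2) is
predicted by a one-hidden-layer logistic MLP and a random forest.  Each base
learner also yields a numeric prediction (the class-probability expectation
sum_c c * p_c).  The two are combined by the relative-MAE gap rule:

    delta = (MAE_mlp - MAE_rf) / max(MAE_mlp, MAE_rf)

computed on the validation split.  If delta <= 0.05 the numeric predictions
are blended with weights Q1 = MAE_mlp / (MAE_mlp + MAE_rf) and
Q2 = 1 - Q1 (each model weighted by its own MAE; the ``inverse_error_weights``
flag swaps to the conventional opposite-error weighting); otherwise the
higher-error model is discarded.  The blended numeric value is decoded to a
class by round-half-down and clamping to {0, 1, 2}.

``evaluate_models`` fits the comparison table of MLP, RF, RF-MLP, RF-SVM and
SVM-MLP (any pair goes through the same gate) with per-split accuracy and
macro one-vs-rest AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import metrics as _metrics
from .dataio import NormalizationState, apply_minmax, fit_minmax
from .schema import ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "MLPConfig",
    "RFConfig",
    "CombinationRule",
    "split_dataset",
    "fit_mlp",
    "fit_rf",
    "fit_svm",
    "combine_rule",
    "predict_combined",
    "fit_ensemble",
    "evaluate_models",
    "EnsembleFit",
]

N_CLASSES = 3


# --------------------------------------------------------------------------
# Splitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Random train/validation/test partition (default 50/20/30)."""

    fractions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    seed: int = 0

    def validate(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.size != 3 or (f <= 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ConfigError("fractions must be 3 positive numbers summing to 1")


def split_dataset(
    dataset: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, seeded uniform split into (train, val, test).

    Train and validation sizes are the rounded fractions; the remainder goes
    to test.
    """
    spec = spec or SplitSpec()
    spec.validate()
    n = len(dataset)
    if n < 10:
        raise ConfigError(f"need at least 10 rows to split, got {n}")
    n_train = round(spec.fractions[0] * n)
    n_val = round(spec.fractions[1] * n)
    perm = np.random.default_rng(spec.seed).permutation(n)
    idx_train = np.sort(perm[:n_train])
    idx_val = np.sort(perm[n_train:n_train + n_val])
    idx_test = np.sort(perm[n_train + n_val:])
    return (
        dataset.iloc[idx_train].reset_index(drop=True),
        dataset.iloc[idx_val].reset_index(drop=True),
        dataset.iloc[idx_test].reset_index(drop=True),
    )


# --------------------------------------------------------------------------
# Base learners
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MLPConfig:
    """One-hidden-layer logistic-activation network."""

    hidden_units: int = 16
    max_epochs: int = 600
    learning_rate_init: float = 1e-3
    solver: str = "lbfgs"
    seed: int = 0

    def validate(self) -> None:
        if self.hidden_units < 1:
            raise ConfigError("hidden_units must be >= 1")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")


@dataclass(frozen=True)
class RFConfig:
    """Bootstrap-resampled forest of classification trees."""

    n_trees: int = 500
    max_depth: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")


class ClassScorePredictor:
    """Wraps a fitted probabilistic classifier over the three behavior classes.

    Exposes per-class scores, the numeric expectation sum_c c * p_c (the
    quantity the combination rule blends), and the argmax class.
    """

    def __init__(self, model, n_classes: int = N_CLASSES):
        self._model = model
        self._n_classes = n_classes

    def scores(self, X: np.ndarray) -> np.ndarray:
        proba = self._model.predict_proba(np.asarray(X, dtype=float))
        full = np.zeros((proba.shape[0], self._n_classes))
        for j, cls in enumerate(self._model.classes_):
            full[:, int(cls)] = proba[:, j]
        return full

    def expectation(self, X: np.ndarray) -> np.ndarray:
        return self.scores(X) @ np.arange(self._n_classes, dtype=float)

    def classes(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.scores(X), axis=1)


def _check_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    return X


def fit_mlp(X: np.ndarray, y: np.ndarray, config: MLPConfig | None = None) -> ClassScorePredictor:
    """Fit the one-hidden-layer logistic MLP on min-max scaled features."""
    config = config or MLPConfig()
    config.validate()
    X = _check_features(X)
    model = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        activation="logistic",
        solver=config.solver,
        learning_rate_init=config.learning_rate_init,
        max_iter=config.max_epochs,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        # max_epochs is a deliberate training-length cap, not a failure.
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        model.fit(X, np.asarray(y, dtype=int))
    return ClassScorePredictor(model)


def fit_rf(X: np.ndarray, y: np.ndarray, config: RFConfig | None = None) -> ClassScorePredictor:
    """Fit the random forest; numeric expectation averages the tree votes."""
    config = config or RFConfig()
    config.validate()
    X = _check_features(X)
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, np.asarray(y, dtype=int))
    return ClassScorePredictor(model)


def fit_svm(X: np.ndarray, y: np.ndarray, seed: int = 0) -> ClassScorePredictor:
    """RBF support-vector classifier with sigmoid-calibrated class scores."""
    X = _check_features(X)
    model = CalibratedClassifierCV(SVC(random_state=seed), method="sigmoid", cv=3)
    model.fit(X, np.asarray(y, dtype=int))
    return ClassScorePredictor(model)


# --------------------------------------------------------------------------
# Combination rule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinationRule:
    """Outcome of the relative-MAE-gap decision for one model pair."""

    mae_1: float                # validation MAE of the first model (MLP role)
    mae_2: float                # validation MAE of the second model (RF role)
    delta: float
    mode: str                   # "combined" | "model1_only" | "model2_only"
    q1: float
    q2: float


def combine_rule(
    mae_1: float,
    mae_2: float,
    threshold: float = 0.05,
    inverse_error_weights: bool = False,
    absolute_delta: bool = False,
) -> CombinationRule:
    """Decide between blending and discarding from two validation MAEs.

    delta = (mae_1 - mae_2) / max(mae_1, mae_2); the boundary delta ==
    threshold blends.  By default each model is weighted by its *own* MAE
    (Q1 = mae_1 / (mae_1 + mae_2)); ``inverse_error_weights`` swaps Q1 and Q2
    so the lower-error model gets the larger weight.  ``absolute_delta`` gates
    on |delta| so a much *better* first model also bypasses blending.  Two
    exactly-zero MAEs blend evenly.
    """
    if mae_1 < 0 or mae_2 < 0:
        raise ValueError("MAE values must be nonnegative")
    if mae_1 == 0.0 and mae_2 == 0.0:
        return CombinationRule(0.0, 0.0, 0.0, "combined", 0.5, 0.5)
    delta = (mae_1 - mae_2) / max(mae_1, mae_2)
    gate = abs(delta) if absolute_delta else delta
    if gate <= threshold:
        q1 = mae_1 / (mae_1 + mae_2)
        q2 = mae_2 / (mae_1 + mae_2)
        if inverse_error_weights:
            q1, q2 = q2, q1
        return CombinationRule(mae_1, mae_2, delta, "combined", q1, q2)
    mode = "model2_only" if mae_1 > mae_2 else "model1_only"
    q1, q2 = (0.0, 1.0) if mode == "model2_only" else (1.0, 0.0)
    return CombinationRule(mae_1, mae_2, delta, mode, q1, q2)


def decode_class(numeric: np.ndarray) -> np.ndarray:
    """Nearest class in {0,1,2}; exact half-points round down."""
    return np.clip(np.ceil(np.asarray(numeric, dtype=float) - 0.5), 0, N_CLASSES - 1).astype(int)


def predict_combined(
    rule: CombinationRule, pred_1: np.ndarray, pred_2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Blend (or gate) two numeric predictions and decode the class."""
    pred_1 = np.asarray(pred_1, dtype=float)
    pred_2 = np.asarray(pred_2, dtype=float)
    numeric = rule.q1 * pred_1 + rule.q2 * pred_2
    return numeric, decode_class(numeric)


# --------------------------------------------------------------------------
# End-to-end fit and model comparison
# --------------------------------------------------------------------------

@dataclass
class EnsembleFit:
    """Fitted ensemble state: base predictors, gate decision, scaling."""

    features: tuple[str, ...]
    norm: NormalizationState
    mlp: ClassScorePredictor
    rf: ClassScorePredictor
    rule: CombinationRule

    def predict(self, X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(numeric, class) combined predictions for a feature table."""
        Xs = apply_minmax(self.norm, X)
        return predict_combined(
            self.rule, self.mlp.expectation(Xs), self.rf.expectation(Xs)
        )

    def combined_scores(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Gate-consistent class-score matrix (used for AUC)."""
        Xs = apply_minmax(self.norm, X)
        return self.rule.q1 * self.mlp.scores(Xs) + self.rule.q2 * self.rf.scores(Xs)


def _evaluate_split(
    report: _metrics.EvaluationReport,
    model: str,
    split: str,
    y: np.ndarray,
    scores: np.ndarray,
    classes: np.ndarray,
    numeric: np.ndarray,
) -> None:
    cm, acc = _metrics.confusion_and_accuracy(y, classes)
    try:
        auc = _metrics.auc_macro_ovr(y, scores)
    except Exception:
        auc = float("nan")
    report.record(
        model, split,
        accuracy=acc, auc=auc, confusion=cm,
        mae=_metrics.mae(y, numeric),
        r2=_metrics.r_squared(y, numeric) if np.ptp(y) > 0 else None,
    )


def fit_ensemble(
    dataset: pd.DataFrame,
    features: list[str] | tuple[str, ...],
    split: SplitSpec | None = None,
    mlp_cfg: MLPConfig | None = None,
    rf_cfg: RFConfig | None = None,
    threshold: float = 0.05,
    inverse_error_weights: bool = False,
    absolute_delta: bool = False,
    target: str = "behavior_class",
) -> tuple[EnsembleFit, _metrics.EvaluationReport]:
    """Fit MLP and RF on the train split, gate on validation MAEs, report all splits."""
    split = split or SplitSpec()
    train, val, test = split_dataset(dataset, split)
    features = tuple(features)

    norm = fit_minmax(train[list(features)])
    parts = {
        name: (apply_minmax(norm, part[list(features)]), part[target].to_numpy(dtype=int))
        for name, part in (("train", train), ("val", val), ("test", test))
    }

    mlp = fit_mlp(*parts["train"], config=mlp_cfg)
    rf = fit_rf(*parts["train"], config=rf_cfg)
    X_val, y_val = parts["val"]
    rule = combine_rule(
        _metrics.mae(y_val, mlp.expectation(X_val)),
        _metrics.mae(y_val, rf.expectation(X_val)),
        threshold=threshold,
        inverse_error_weights=inverse_error_weights,
        absolute_delta=absolute_delta,
    )
    fit = EnsembleFit(features=features, norm=norm, mlp=mlp, rf=rf, rule=rule)

    report = _metrics.EvaluationReport()
    for name, (X, y) in parts.items():
        numeric, classes = predict_combined(rule, mlp.expectation(X), rf.expectation(X))
        scores = rule.q1 * mlp.scores(X) + rule.q2 * rf.scores(X)
        _evaluate_split(report, "RF-MLP", name, y, scores, classes, numeric)
    return fit, report


def evaluate_models(
    dataset: pd.DataFrame,
    features: list[str] | tuple[str, ...],
    split: SplitSpec | None = None,
    mlp_cfg: MLPConfig | None = None,
    rf_cfg: RFConfig | None = None,
    threshold: float = 0.05,
    target: str = "behavior_class",
) -> _metrics.EvaluationReport:
    """Comparison table of MLP, RF, RF-MLP, RF-SVM and SVM-MLP.

    Every hyphenated pair uses the same validation-MAE gate; in "A-B" the B
    model plays the MLP role of the rule (MAE_1) and A the RF role (MAE_2),
    mirroring the RF-MLP naming.
    """
    split = split or SplitSpec()
    mlp_cfg = mlp_cfg or MLPConfig()
    rf_cfg = rf_cfg or RFConfig()
    train, val, test = split_dataset(dataset, split)
    features = tuple(features)

    norm = fit_minmax(train[list(features)])
    parts = {
        name: (apply_minmax(norm, part[list(features)]), part[target].to_numpy(dtype=int))
        for name, part in (("train", train), ("val", val), ("test", test))
    }
    X_train, y_train = parts["train"]
    X_val, y_val = parts["val"]

    base = {
        "MLP": fit_mlp(X_train, y_train, mlp_cfg),
        "RF": fit_rf(X_train, y_train, rf_cfg),
        "SVM": fit_svm(X_train, y_train, seed=rf_cfg.seed),
    }
    report = _metrics.EvaluationReport()
    for name in ("MLP", "RF"):
        predictor = base[name]
        for part, (X, y) in parts.items():
            _evaluate_split(
                report, name, part, y,
                predictor.scores(X), predictor.classes(X), predictor.expectation(X),
            )

    pairs = {"RF-MLP": ("MLP", "RF"), "RF-SVM": ("SVM", "RF"), "SVM-MLP": ("MLP", "SVM")}
    for pair_name, (first, second) in pairs.items():
        rule = combine_rule(
            _metrics.mae(y_val, base[first].expectation(X_val)),
            _metrics.mae(y_val, base[second].expectation(X_val)),
            threshold=threshold,
        )
        for part, (X, y) in parts.items():
            numeric, classes = predict_combined(
                rule, base[first].expectation(X), base[second].expectation(X)
            )
            scores = rule.q1 * base[first].scores(X) + rule.q2 * base[second].scores(X)
            _evaluate_split(report, pair_name, part, y, scores, classes, numeric)
    return report
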