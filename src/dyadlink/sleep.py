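"""Random-forest prediction of infant sleep outcomes from maternal indicators.

Targets: the FCM-derived ordinal sleep-quality label, the binned nightly
sleep time, the wake count, and the sleep-onset mode.  Categorical targets
use classification forests (evaluated by accuracy/confusion), the wake count
a regression forest (MAE / R^2).  Default feature lists follow the screening
outcome: maternal age, education, EPDS and HADS for quality/sleep-time/mode;
EPDS, HADS, delivery mode and infant age (the Spearman-selected set) for the
wake count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from . import metrics as _metrics
from .ensemble import RFConfig, SplitSpec, split_dataset
from .schema import ConfigError, SchemaError

logger = logging.getLogger(__name__)

__all__ = ["SleepTargetSpec", "SleepPredictor", "fit_sleep_model", "predict_unlabeled"]

TARGETS = ("quality_label", "sleep_time_class", "wake_times", "sleep_mode")

DEFAULT_FEATURES: dict[str, tuple[str, ...]] = {
    "quality_label": ("maternal_age", "education", "epds", "hads"),
    "sleep_time_class": ("maternal_age", "education", "epds", "hads"),
    "wake_times": ("epds", "hads", "delivery_mode", "infant_age"),
    "sleep_mode": ("maternal_age", "education", "epds", "hads"),
}


@dataclass(frozen=True)
class SleepTargetSpec:
    """One sleep-outcome modelling task: target, features, forest settings."""

    target: str
    features: tuple[str, ...] = ()
    rf: RFConfig = field(default_factory=RFConfig)
    sleep_time_edges: tuple[float, ...] | None = None  # None -> train tertiles

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ConfigError(f"unknown target '{self.target}'; expected one of {TARGETS}")
        if not self.features:
            object.__setattr__(self, "features", DEFAULT_FEATURES[self.target])


@dataclass
class SleepPredictor:
    """Fitted forest plus the metadata needed to score new dyads."""

    spec: SleepTargetSpec
    model: RandomForestClassifier | RandomForestRegressor
    kind: str                       # "classification" | "regression"
    classes: np.ndarray | None      # label codes, classification only
    sleep_time_edges: np.ndarray | None


def _target_vector(
    dataset: pd.DataFrame, spec: SleepTargetSpec, edges: np.ndarray | None
) -> np.ndarray:
    if spec.target == "quality_label":
        if "quality_label" not in dataset.columns:
            raise ConfigError(
                "dataset lacks a 'quality_label' column; run the FCM stage first"
            )
        col = dataset["quality_label"]
        if col.dtype == object:
            codes = {"good": 0, "moderate": 1, "poor": 2}
            return col.map(codes).to_numpy(dtype=int)
        return col.to_numpy(dtype=int)
    if spec.target == "sleep_time_class":
        assert edges is not None
        return np.digitize(dataset["sleep_time"].to_numpy(dtype=float), edges)
    return dataset[spec.target].to_numpy(
        dtype=float if spec.target == "wake_times" else int
    )


def fit_sleep_model(
    dataset: pd.DataFrame,
    spec: SleepTargetSpec,
    split: SplitSpec | None = None,
) -> tuple[SleepPredictor, _metrics.EvaluationReport]:
    """Fit a seeded forest for one sleep target and report all three splits.

    The sleep-time target is discretized by hour edges (given, or the train
    split's tertiles) before classification.
    """
    split = split or SplitSpec()
    train, val, test = split_dataset(dataset, split)

    edges = None
    if spec.target == "sleep_time_class":
        if spec.sleep_time_edges is not None:
            edges = np.asarray(spec.sleep_time_edges, dtype=float)
        else:
            edges = np.quantile(train["sleep_time"].to_numpy(dtype=float), [1 / 3, 2 / 3])

    regression = spec.target == "wake_times"
    cls = RandomForestRegressor if regression else RandomForestClassifier
    model = cls(
        n_estimators=spec.rf.n_trees,
        max_depth=spec.rf.max_depth,
        random_state=spec.rf.seed,
        n_jobs=1,
    )
    X_train = train[list(spec.features)].to_numpy(dtype=float)
    y_train = _target_vector(train, spec, edges)
    model.fit(X_train, y_train)

    predictor = SleepPredictor(
        spec=spec,
        model=model,
        kind="regression" if regression else "classification",
        classes=None if regression else model.classes_,
        sleep_time_edges=edges,
    )

    report = _metrics.EvaluationReport()
    model_name = f"RF[{spec.target}]"
    for name, part in (("train", train), ("val", val), ("test", test)):
        X = part[list(spec.features)].to_numpy(dtype=float)
        y = _target_vector(part, spec, edges)
        if regression:
            pred = model.predict(X)
            report.record(
                model_name, name,
                mae=_metrics.mae(y, pred),
                r2=_metrics.r_squared(y, pred) if np.ptp(y) > 0 else None,
            )
        else:
            pred = model.predict(X)
            labels = tuple(int(c) for c in np.union1d(model.classes_, np.unique(y)))
            cm, acc = _metrics.confusion_and_accuracy(y, pred, labels=labels)
            try:
                auc = _metrics.auc_macro_ovr(
                    y, _full_scores(model, X, labels)
                )
            except Exception:
                auc = float("nan")
            report.record(model_name, name, accuracy=acc, auc=auc, confusion=cm)
    return predictor, report


def _full_scores(model, X: np.ndarray, labels: tuple[int, ...]) -> np.ndarray:
    proba = model.predict_proba(X)
    full = np.zeros((len(X), max(labels) + 1))
    for j, cls in enumerate(model.classes_):
        full[:, int(cls)] = proba[:, j]
    return full


def predict_unlabeled(
    predictor: SleepPredictor, maternal: pd.DataFrame
) -> pd.DataFrame:
    """One prediction row per unlabeled dyad, with class scores when defined.

    Input columns are realigned by name, so column order does not matter; a
    missing feature raises :class:`SchemaError`.
    """
    features = list(predictor.spec.features)
    missing = [f for f in features if f not in maternal.columns]
    if missing:
        raise SchemaError(f"input lacks feature column(s): {', '.join(missing)}")
    X = maternal[features].to_numpy(dtype=float)
    out = pd.DataFrame()
    if "dyad_id" in maternal.columns:
        out["dyad_id"] = maternal["dyad_id"].to_numpy()
    else:
        out["dyad_id"] = np.arange(1, len(maternal) + 1)
    prediction = predictor.model.predict(X)
    out[f"pred_{predictor.spec.target}"] = prediction
    if predictor.kind == "classification":
        proba = predictor.model.predict_proba(X)
        for j, cls in enumerate(predictor.model.classes_):
            out[f"score_{int(cls)}"] = proba[:, j]
    return out
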