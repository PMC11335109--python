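"""End-to-end orchestration: simulate/ingest -> clean -> correlate ->
select features -> fit behavior ensemble -> cluster sleep -> fit sleep models.

Each stage reads its inputs from, and writes its artifacts into, a single
report directory, so stages can be run individually (the CLI subcommands) or
end to end with identical results.  A manifest records the configuration,
its hash, the per-stage seeds and package versions; two runs with the same
configuration produce byte-identical manifests and artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import correlation as _correlation
from . import dataio as _dataio
from . import ensemble as _ensemble
from . import fcm as _fcm
from . import features as _features
from . import sleep as _sleep
from . import synthetic as _synthetic
from .schema import MATERNAL_FEATURES, SLEEP_FEATURES, ConfigError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = (
    "simulate",
    "clean",
    "correlate",
    "select-features",
    "fit-behavior",
    "cluster-sleep",
    "fit-sleep",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Flat-key pipeline configuration (loadable from a YAML file).

    Exactly one of ``input_path`` (an existing dyad CSV) or ``n_dyads``
    (synthetic generation) must be set.  Every stage has its own seed so
    stages are independently reproducible.
    """

    input_path: str | None = None
    n_dyads: int | None = 410
    n_outliers: int = 31          # injected into synthetic data before cleaning
    n_unlabeled: int = 20         # trailing dyads scored as the unlabeled batch
    k_features: int = 4
    threshold: float = 0.05
    inverse_error_weights: bool = False
    absolute_delta: bool = False
    fcm_m: float = 2.0
    fcm_c_min: int = 2
    fcm_c_max: int = 6
    fcm_restarts: int = 5
    seed_generate: int = 2024
    seed_split: int = 1
    seed_model: int = 7
    seed_fcm: int = 11
    out_dir: str = "dyadlink_report"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if (self.input_path is None) == (self.n_dyads is None):
            raise ConfigError("exactly one of input_path / n_dyads must be set")
        if self.fcm_c_min < 2 or self.fcm_c_max < self.fcm_c_min:
            raise ConfigError("fcm_c range must satisfy 2 <= c_min <= c_max")
        if not 1 <= self.k_features <= len(MATERNAL_FEATURES):
            raise ConfigError(f"k_features must be in [1, {len(MATERNAL_FEATURES)}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        unknown = {k: v for k, v in raw.items() if k not in known}
        if unknown:
            logger.warning("ignoring unknown config key(s): %s", sorted(unknown))
        if "input_path" in kwargs and kwargs["input_path"] is not None:
            kwargs.setdefault("n_dyads", None)
        return cls(**kwargs, extra=unknown) if "extra" not in kwargs else cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("extra", None)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _out(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> Path:
    """Generate (or copy in) the raw dyad table."""
    config.validate()
    out = _out(config)
    raw_path = out / "raw.csv"
    if config.input_path is not None:
        df = _dataio.read_dyads(config.input_path)
    else:
        gen = _synthetic.GeneratorConfig(n_dyads=config.n_dyads, seed=config.seed_generate)
        df = _synthetic.generate_dataset(gen)
        if config.n_outliers:
            df, mutated = _synthetic.inject_outliers(
                df, config.n_outliers, seed=config.seed_generate + 1
            )
            _write_json(out / "injected_outliers.json", {"dyad_ids": mutated})
    _dataio.write_dyads(df, raw_path)
    return raw_path


def stage_clean(config: PipelineConfig) -> Path:
    out = _out(config)
    df = _dataio.read_dyads(out / "raw.csv")
    clean, removed = _dataio.remove_outliers(df)
    _dataio.write_dyads(clean, out / "clean.csv")
    _write_json(out / "removed.json", {"n_removed": len(removed), "dyad_ids": removed})
    return out / "clean.csv"


def stage_correlate(config: PipelineConfig) -> Path:
    out = _out(config)
    df = _dataio.read_dyads(out / "clean.csv")
    matrix = _correlation.correlation_matrix(df)
    matrix.to_csv(out / "correlation_matrix.csv")
    matrix.pairs.to_csv(out / "correlation_pairs.csv", index=False)
    return out / "correlation_matrix.csv"


def stage_select_features(config: PipelineConfig) -> Path:
    out = _out(config)
    df = _dataio.read_dyads(out / "clean.csv")
    labeled = df.iloc[: len(df) - config.n_unlabeled] if config.n_unlabeled else df
    report = _features.tree_importances(
        labeled[list(MATERNAL_FEATURES)],
        labeled["behavior_class"],
        seed=config.seed_model,
        target_name="behavior_class",
    )
    report.to_frame().to_csv(out / "behavior_importance.csv", index=False)
    selected = _features.select_features(report, k=config.k_features)
    _write_json(out / "selected_features.json", {
        "behavior_class": selected,
        "wake_times": list(_sleep.DEFAULT_FEATURES["wake_times"]),
    })
    return out / "selected_features.json"


def stage_fit_behavior(config: PipelineConfig) -> Path:
    out = _out(config)
    df = _dataio.read_dyads(out / "clean.csv")
    labeled = df.iloc[: len(df) - config.n_unlabeled] if config.n_unlabeled else df
    selected = json.loads((out / "selected_features.json").read_text())["behavior_class"]
    split = _ensemble.SplitSpec(seed=config.seed_split)
    mlp_cfg = _ensemble.MLPConfig(seed=config.seed_model)
    rf_cfg = _ensemble.RFConfig(seed=config.seed_model)

    fit, _ = _ensemble.fit_ensemble(
        labeled, selected, split, mlp_cfg, rf_cfg,
        threshold=config.threshold,
        inverse_error_weights=config.inverse_error_weights,
        absolute_delta=config.absolute_delta,
    )
    comparison = _ensemble.evaluate_models(
        labeled, selected, split, mlp_cfg, rf_cfg, threshold=config.threshold
    )
    comparison.to_frame().to_csv(out / "model_comparison.csv", index=False)
    (out / "behavior_report.json").write_text(comparison.to_json() + "\n")
    _write_json(out / "combination_rule.json", {
        "mae_mlp": fit.rule.mae_1, "mae_rf": fit.rule.mae_2,
        "delta": fit.rule.delta, "mode": fit.rule.mode,
        "q1": fit.rule.q1, "q2": fit.rule.q2,
    })
    if config.n_unlabeled:
        unlabeled = df.iloc[len(df) - config.n_unlabeled:]
        numeric, classes = fit.predict(unlabeled[list(fit.features)])
        pd.DataFrame({
            "dyad_id": unlabeled["dyad_id"].to_numpy(),
            "pred_numeric": numeric,
            "pred_behavior_class": classes,
        }).to_csv(out / "behavior_predictions.csv", index=False)
    return out / "model_comparison.csv"


def stage_cluster_sleep(config: PipelineConfig) -> Path:
    out = _out(config)
    df = _dataio.read_dyads(out / "clean.csv")
    labeled = df.iloc[: len(df) - config.n_unlabeled] if config.n_unlabeled else df
    norm = _dataio.fit_minmax(labeled[list(SLEEP_FEATURES)])
    X = _dataio.apply_minmax(norm, labeled[list(SLEEP_FEATURES)])

    fcm_cfg = _fcm.FCMConfig(m=config.fcm_m, seed=config.seed_fcm, n_restarts=config.fcm_restarts)
    curve = _fcm.silhouette_curve(X, range(config.fcm_c_min, config.fcm_c_max + 1), fcm_cfg)
    pd.DataFrame(curve, columns=["c", "silhouette"]).to_csv(
        out / "silhouette_curve.csv", index=False
    )
    best_c = _fcm.best_cluster_count(curve)

    result = _fcm.fcm_fit(X, dataclasses.replace(fcm_cfg, c=3))
    labels = _fcm.label_sleep_quality(result, SLEEP_FEATURES)
    counts = pd.Series(labels).value_counts().to_dict()
    _write_json(out / "sleep_clusters.json", {
        "selected_c": int(best_c),
        "labelled_c": 3,
        "centers": result.centers.tolist(),
        "objective": result.objective,
        "n_iter": result.n_iter,
        "class_counts": {k: int(v) for k, v in counts.items()},
    })
    members = pd.DataFrame(
        result.membership, columns=[f"u_cluster{j}" for j in range(3)]
    )
    members.insert(0, "dyad_id", labeled["dyad_id"].to_numpy())
    members["quality_label"] = labels
    members.to_csv(out / "sleep_memberships.csv", index=False)
    return out / "sleep_clusters.json"


def stage_fit_sleep(config: PipelineConfig) -> Path:
    out = _out(config)
    df = _dataio.read_dyads(out / "clean.csv")
    labeled = df.iloc[: len(df) - config.n_unlabeled].copy() if config.n_unlabeled else df.copy()
    members = pd.read_csv(out / "sleep_memberships.csv")
    labeled = labeled.merge(members[["dyad_id", "quality_label"]], on="dyad_id")

    split = _ensemble.SplitSpec(seed=config.seed_split)
    reports = {}
    predictions = []
    for target in _sleep.TARGETS:
        spec = _sleep.SleepTargetSpec(
            target=target, rf=_ensemble.RFConfig(seed=config.seed_model)
        )
        predictor, report = _sleep.fit_sleep_model(labeled, spec, split)
        reports[target] = json.loads(report.to_json())
        if config.n_unlabeled:
            unlabeled = df.iloc[len(df) - config.n_unlabeled:]
            pred = _sleep.predict_unlabeled(predictor, unlabeled)
            predictions.append(pred.set_index("dyad_id")[f"pred_{target}"])
    _write_json(out / "sleep_model_report.json", reports)
    if predictions:
        pd.concat(predictions, axis=1).reset_index().to_csv(
            out / "sleep_predictions.csv", index=False
        )
    return out / "sleep_model_report.json"


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "clean": stage_clean,
    "correlate": stage_correlate,
    "select-features": stage_select_features,
    "fit-behavior": stage_fit_behavior,
    "cluster-sleep": stage_cluster_sleep,
    "fit-sleep": stage_fit_sleep,
}


def run_stage(name: str, config: PipelineConfig) -> Path:
    if name not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage '{name}'; expected one of {STAGES}")
    return _STAGE_FUNCS[name](config)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order and write the manifest; returns the report dir."""
    config.validate()
    out = _out(config)
    completed = []
    for name in STAGES:
        try:
            run_stage(name, config)
        except Exception:
            logger.error("pipeline halted at stage '%s'; partial outputs kept in %s",
                         name, out)
            raise
        completed.append(name)
    _write_json(out / "manifest.json", {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": {
            "generate": config.seed_generate,
            "split": config.seed_split,
            "model": config.seed_model,
            "fcm": config.seed_fcm,
        },
        "stages": completed,
        "versions": {
            "dyadlink": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    })
    return out
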