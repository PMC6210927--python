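"""Default pipeline configuration: the tuned classifier settings and the
accepted TUG sequence templates.

The four classifier configurations (method, window geometry, noise filter and
feature set per level) are the tuned operating point of the hierarchy; the
default model set lives in :mod:`tugsense.grammar`.  Everything is plain data
so variants can be expressed in a config file rather than code.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from .features import FeatureSpec, WindowSpec
from .grammar import DEFAULT_MODEL_SET, TugModelSet, TugTemplate
from .model import ClassifierConfig
from .recording import FilterSpec

__all__ = [
    "DEFAULT_CONFIGS",
    "RunConfig",
    "default_configs",
    "config_from_dict",
    "config_hash",
]


def default_configs() -> dict[str, ClassifierConfig]:
    """The tuned configuration of the four classifiers.

    State routing uses boosted decision trees on a fine 72 ms step; the three
    specialists are multilayer perceptrons (hidden layers x nodes: 5x7 static,
    3x44 dynamic, 4x40 transition), each with its own window and filter.
    """
    return {
        "state": ClassifierConfig(
            level="state",
            method="boosted_decision_trees",
            window=WindowSpec(1.405, 0.072),
            filter=FilterSpec("lowpass", cutoff_hz=6.1),
            features=(
                FeatureSpec("autocorrelation", "acc+gyro"),
                FeatureSpec("correlation", "acc+gyro"),
                FeatureSpec("mean", "acc"),
                FeatureSpec("rms", "acc+gyro"),
                FeatureSpec("sd", "acc+gyro"),
                FeatureSpec("signal_energy", "acc+gyro"),
            ),
            hyperparams={"rounds": 200, "depth": 3},
        ),
        "static": ClassifierConfig(
            level="static",
            method="multilayer_perceptron",
            window=WindowSpec(2.511, 0.427),
            filter=FilterSpec("none"),
            features=(
                FeatureSpec("mean", "acc"),
                FeatureSpec("sma", "acc"),
                FeatureSpec("pitch", "acc"),
                FeatureSpec("autocorrelation", "acc+gyro"),
                FeatureSpec("correlation", "acc+gyro"),
            ),
            hyperparams={"hidden_layers": 5, "hidden_nodes": 7, "max_iter": 400},
        ),
        "dynamic": ClassifierConfig(
            level="dynamic",
            method="multilayer_perceptron",
            window=WindowSpec(1.853, 0.249),
            filter=FilterSpec("gaussian", sigma_s=0.23),
            features=(
                FeatureSpec("rms", "acc"),
                FeatureSpec("pitch", "acc"),
                FeatureSpec("autocorrelation", "acc+gyro"),
                FeatureSpec("correlation", "acc+gyro"),
                FeatureSpec("sma", "acc+gyro"),
                FeatureSpec("sd", "acc+gyro"),
            ),
            hyperparams={"hidden_layers": 3, "hidden_nodes": 44, "max_iter": 400},
        ),
        "transition": ClassifierConfig(
            level="transition",
            method="multilayer_perceptron",
            window=WindowSpec(1.135, 0.073),
            filter=FilterSpec("lowpass", cutoff_hz=4.5),
            features=(
                FeatureSpec("rms", "acc"),
                FeatureSpec("mean", "gyro"),
                FeatureSpec("signal_energy", "gyro"),
                FeatureSpec("autocorrelation", "acc+gyro"),
                FeatureSpec("correlation", "acc+gyro"),
                FeatureSpec("sma", "acc+gyro"),
                FeatureSpec("sd", "acc+gyro"),
                FeatureSpec("pitch", "acc"),
            ),
            hyperparams={"hidden_layers": 4, "hidden_nodes": 40, "max_iter": 400},
        ),
    }


DEFAULT_CONFIGS = default_configs()


@dataclass
class RunConfig:
    """End-to-end pipeline settings with the tuned defaults built in."""

    classifiers: dict = field(default_factory=default_configs)
    model_set: TugModelSet = DEFAULT_MODEL_SET
    min_segment_s: float = 0.5
    max_tug_duration_s: float = 30.0
    boundary_min_s: float = 1.0
    seed: int = 0


def _filter_from_dict(d: dict) -> FilterSpec:
    return FilterSpec(
        d.get("kind", "none"), cutoff_hz=d.get("cutoff_hz"), sigma_s=d.get("sigma_s")
    )


def config_from_dict(doc: dict) -> RunConfig:
    """Build a RunConfig from a parsed config-file mapping.

    Only keys present in the document override the defaults, so a config file
    can patch a single classifier or just the thresholds.
    """
    cfg = RunConfig()
    for level, spec in doc.get("classifiers", {}).items():
        base = cfg.classifiers[level]
        cfg.classifiers[level] = ClassifierConfig(
            level=level,
            method=spec.get("method", base.method),
            window=WindowSpec(
                spec.get("window_size_s", base.window.size_s),
                spec.get("step_s", base.window.step_s),
            ),
            filter=_filter_from_dict(spec["filter"]) if "filter" in spec else base.filter,
            features=tuple(
                FeatureSpec(f["feature"], f.get("channels", "acc"))
                for f in spec["features"]
            )
            if "features" in spec
            else base.features,
            hyperparams=spec.get("hyperparams", dict(base.hyperparams)),
            autocorr_lag_s=spec.get("autocorr_lag_s", base.autocorr_lag_s),
        )
    if "templates" in doc:
        cfg.model_set = TugModelSet(
            templates=tuple(
                TugTemplate.from_notation(i + 1, s) for i, s in enumerate(doc["templates"])
            ),
            accuracies=tuple(doc["template_accuracies"])
            if "template_accuracies" in doc
            else None,
        )
    for key in ("min_segment_s", "max_tug_duration_s", "boundary_min_s", "seed"):
        if key in doc:
            setattr(cfg, key, doc[key])
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of a run configuration, for logging."""
    doc = {
        "classifiers": {
            level: {
                "method": c.method,
                "window": [c.window.size_s, c.window.step_s],
                "filter": [c.filter.kind, c.filter.cutoff_hz, c.filter.sigma_s],
                "features": [[f.feature, f.channels] for f in c.features],
                "hyperparams": dict(sorted(c.hyperparams.items())),
                "autocorr_lag_s": c.autocorr_lag_s,
            }
            for level, c in sorted(cfg.classifiers.items())
        },
        "templates": [t.notation for t in cfg.model_set.templates],
        "thresholds": [cfg.min_segment_s, cfg.max_tug_duration_s, cfg.boundary_min_s],
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]
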