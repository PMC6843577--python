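"""Run configuration: YAML schema validation and resolved-config snapshots.

Unknown keys are rejected so typos fail fast; every pipeline run writes the
fully resolved configuration next to its outputs for replay.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

__all__ = ["ConfigError", "DEFAULT_CONFIG", "load_config", "resolve_config", "write_resolved"]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


DEFAULT_CONFIG: dict[str, Any] = {
    "paths": {
        "compounds": None,       # compound CSV; when unset, synthetic mode
        "output_dir": "runs/latest",
        "model_dir": None,
    },
    "featurize": {
        "families": ["EStateFP", "MACCSFP", "2D Descriptor"],
        "backend": "rdkit",      # rdkit | hashed
    },
    "synth": {
        "n": 200,
        "p_informative": 5,
        "p_redundant": 5,
        "p_noise": 10,
        "class_balance": 0.5,
        "effect_size": 1.5,
        "redundancy_rho": 0.95,
        "value_kind": "continuous",
        "n_families": 3,         # pseudo-families generated in synthetic mode
    },
    "selection": {
        "correlation_cutoff": 0.90,
        "boruta_max_iter": 100,
        "boruta_alpha": 0.05,
        "rfe_step": 1,
        "rf_estimators": 100,    # importance estimator size (Boruta + RFE)
        "use_boruta": True,
    },
    "learners": [
        "naive_bayes", "svm_rbf", "knn", "kstar",
        "adaboost_tree", "bagging_knn", "decision_tree", "random_forest",
    ],
    "tune": {"enabled": False, "grids": None},
    "cv": {"k": 10, "stratified": True, "seed": 0},
    "ensemble": {"meta_feature_mode": "out_of_fold"},
    "screening": {
        "threshold": 0.500,
        "herb": None,
        "network": None,
        "hili": None,
        "no_classifier": False,
    },
    "yrand": {"runs": 100},
    "log_level": "INFO",
    "seed": 0,
    "package_version": None,  # stamped into resolved snapshots
}


def _merge(base: Mapping[str, Any], override: Mapping[str, Any], path: str = "") -> dict:
    out = copy.deepcopy(dict(base))
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here!r}")
        if isinstance(base[key], Mapping) and isinstance(value, Mapping):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: Optional[str | Path] = None) -> dict[str, Any]:
    """Defaults merged with a YAML file (if given); unknown keys rejected."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration file must contain a mapping")
    return _merge(DEFAULT_CONFIG, raw)


def resolve_config(path: Optional[str | Path] = None, **overrides) -> dict[str, Any]:
    """load_config plus dotted-key overrides (e.g. ``cv.seed=3``)."""
    cfg = load_config(path)
    for dotted, value in overrides.items():
        if value is None:
            continue
        keys = dotted.split("__")
        node = cfg
        for k in keys[:-1]:
            if k not in node:
                raise ConfigError(f"unknown configuration key: {dotted!r}")
            node = node[k]
        if keys[-1] not in node:
            raise ConfigError(f"unknown configuration key: {dotted!r}")
        node[keys[-1]] = value
    return cfg


def write_resolved(cfg: Mapping[str, Any], out_dir: str | Path) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snapshot = dict(copy.deepcopy(dict(cfg)), package_version=__version__)
    target = out_dir / "resolved_config.yaml"
    target.write_text(yaml.safe_dump(snapshot, sort_keys=True))
    return target
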