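"""Pipeline configuration: a single YAML file drives every subcommand.

The shipped defaults reproduce the published settings wherever they are
stated: the CombiWISE coefficients, the per-class efficacy lines with the
zero clamp, the 2:1 stratified split, and the boosting hyperparameters
(interaction depth 2, shrinkage 0.001, half-sample bagging, tree count by
five-fold cross-validation).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .cohort import ValidationError

__all__ = ["default_config", "load_config", "save_config", "config_hash"]

_DEFAULTS = {
    "paths": {
        "cohort_dir": "cohort",  # demographics/visits/treatments CSVs live here
        "out_dir": "results",
    },
    "efficacy": {
        # percent efficacy = slope * mean_age + intercept, per class
        "class_coefficients": {
            "none_or_unknown": [0.0, 0.0],
            "low": [-1.50, 83.71],
            "high": [-4.34, 206.39],
        },
        "cap": 0.95,
    },
    "reference": {
        "disease_duration_bin_years": 1.0,
        "age_bin_years": 5.0,
        "min_bin_count": 5,
    },
    "split": {
        "train_fraction": 0.6666666666666666,
        "seed": 0,
    },
    "gbm": {
        "interaction_depth": 2,
        "shrinkage": 0.001,
        "bag_fraction": 0.5,
        "cv_folds": 5,
        "tree_grid": [100, 200, 400, 800, 1600, 3200, 6400, 12800, 20000],
        "influence_threshold": 4.0,
        "seed": 0,
    },
    "stability": {
        "n_partitions": 100,
        "seed": 0,
        # scaled-down boosting settings for the repeated-partition check
        "gbm": {"shrinkage": 0.01, "tree_grid": [400], "cv_folds": 5},
    },
    "simulate": {
        "n_patients": 201,
        "seed": 1,
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None) -> dict:
    """Defaults overlaid with the user's YAML file (missing keys keep defaults)."""
    cfg = default_config()
    if path is None:
        return cfg
    loaded = yaml.safe_load(Path(path).read_text())
    if loaded is None:
        return cfg
    if not isinstance(loaded, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return _merge(cfg, loaded)


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def efficacy_model_from_config(cfg: dict):
    from .therapy import EfficacyModel

    eff = cfg["efficacy"]
    return EfficacyModel(
        class_coefficients={k: tuple(v) for k, v in eff["class_coefficients"].items()},
        cap=float(eff["cap"]),
    )
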