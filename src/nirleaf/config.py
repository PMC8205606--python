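"""Run configuration: a flat key-value tree loaded from YAML.

Sections mirror the pipeline stages (synth/data, pipeline, split, model,
training, evaluation) plus a ``master_seed``.  Unknown keys are rejected
with the offending key named, so typos fail loudly before any computation.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["DEFAULT_CONFIG", "load_config", "resolve_config", "dump_config"]

# section -> known keys; pipeline step params are validated dynamically
_SCHEMA: dict[str, set | None] = {
    "master_seed": None,
    "synth": {"preset", "position", "n_per_class", "n_spots", "noise_sd",
              "scatter_add_sd", "baseline_slope_sd", "scatter_mult_lo",
              "scatter_mult_hi", "seed"},
    "data": {"input"},
    "pipeline": None,  # free-form flat step config ("steps", "<step>.<param>")
    "split": {"fraction", "on", "metric"},
    "model": {"name", "n_hidden", "k", "metric", "C", "gamma", "kernel_size",
              "learning_rate", "epochs"},
    "training": {"n_runs", "batch_size", "epochs", "learning_rate"},
    "evaluation": {"out_dir"},
}

DEFAULT_CONFIG: dict = {
    "master_seed": 0,
    "synth": {"preset": "easy_benchmark", "position": "upper", "n_per_class": 56},
    "pipeline": {"steps": "sg_derivative,minmax_norm",
                 "sg_derivative.window": 59,
                 "sg_derivative.polyorder": 2,
                 "sg_derivative.deriv": 1,
                 "sg_derivative.mode": "valid"},
    "split": {"fraction": 0.7, "on": "preprocessed", "metric": "euclidean"},
    "model": {"name": "elm", "n_hidden": 150},
    "training": {"n_runs": 5},
    "evaluation": {},
}

_PIPELINE_STEPS = ("sg_smooth", "sg_derivative", "snv", "msc", "minmax_norm",
                   "unit_norm", "trim")


def _validate(cfg: dict) -> None:
    for section, value in cfg.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config key {section!r}")
        allowed = _SCHEMA[section]
        if allowed is None:
            if section == "pipeline" and isinstance(value, dict):
                for key in value:
                    if key == "steps":
                        continue
                    step = key.split(".", 1)[0]
                    if "." not in key or step not in _PIPELINE_STEPS:
                        raise ConfigError(f"unknown config key 'pipeline.{key}'")
            continue
        if not isinstance(value, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key in value:
            if key not in allowed:
                raise ConfigError(f"unknown config key '{section}.{key}'")


def resolve_config(overrides: dict | None = None) -> dict:
    """Defaults overlaid with ``overrides``; validated against the schema."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for section, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(value)
        else:
            cfg[section] = value
    _validate(cfg)
    return cfg


def load_config(path) -> dict:
    """Load a YAML config file and resolve it over the defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return resolve_config(raw)


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=True)
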