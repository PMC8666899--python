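"""Pipeline configuration: YAML schema, defaults and validation.

Every tunable in the pipeline has a documented default; unknown keys are
rejected so typos fail loudly before any computation.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .core import ConfigurationError

DEFAULTS: dict = {
    "seed": 0,
    "simulate": {
        "n_subjects": 5,
        "duration": 300.0,
        "ip_rate": 62.5,
        "numeric_rate": 1.0,
        "breath_rate_mean": 50.0,
        "breath_rate_jitter": 0.05,
        "breath_amplitude": 1.0,
        "amplitude_drift": 0.05,
        "cardiac_rate": 150.0,
        "cardiac_amplitude_ratio": 0.2,
        "noise_sd": 0.05,
        "hr_baseline": 150.0,
        "spo2_baseline": 97.0,
    },
    "preprocess": {
        "baseline_cutoff_hz": 0.1,
        "k_mad": 6.0,
        "mask_pad_s": 0.5,
        "mad_window_s": 30.0,
        "notch_halfwidth_hz": 0.3,
    },
    "breaths": {
        "alpha": 0.4,
        "n_breaths": 15,
        "refractory_s": 0.3,
        "init_window_s": 15.0,
        "max_artefact_overlap": 0.1,
    },
    "apnoea": {
        "ibi_threshold_s": 20.0,
        "svm_c": 1.0,
        "pre_window_s": 10.0,
        "post_window_s": 10.0,
        "response_window_s": 60.0,
    },
    "stats": {
        "n_permutations": 10000,
        "alternative": "two-sided",
        "pause_threshold_s": 5.0,
        "rr_window_s": 30.0,
    },
}

_POSITIVE = {
    ("simulate", "duration"),
    ("simulate", "ip_rate"),
    ("simulate", "numeric_rate"),
    ("preprocess", "baseline_cutoff_hz"),
    ("preprocess", "k_mad"),
    ("preprocess", "mad_window_s"),
    ("preprocess", "notch_halfwidth_hz"),
    ("breaths", "alpha"),
    ("breaths", "refractory_s"),
    ("breaths", "init_window_s"),
    ("apnoea", "ibi_threshold_s"),
    ("apnoea", "svm_c"),
    ("stats", "pause_threshold_s"),
    ("stats", "rr_window_s"),
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigurationError(f"unknown config key {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(f"config key {here!r} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def validate_config(config: dict) -> None:
    for section, key in _POSITIVE:
        if config[section][key] <= 0:
            raise ConfigurationError(f"{section}.{key} must be > 0")
    if config["breaths"]["n_breaths"] < 1:
        raise ConfigurationError("breaths.n_breaths must be >= 1")
    if not 0 <= config["breaths"]["max_artefact_overlap"] <= 1:
        raise ConfigurationError("breaths.max_artefact_overlap must lie in [0, 1]")
    if config["stats"]["n_permutations"] < 100:
        raise ConfigurationError("stats.n_permutations must be >= 100")
    if config["stats"]["alternative"] not in ("two-sided", "greater", "less"):
        raise ConfigurationError("stats.alternative must be two-sided, greater or less")


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML file and/or an override mapping into the defaults."""
    config = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config file must contain a mapping")
        config = _merge(config, loaded)
    if overrides:
        config = _merge(config, overrides)
    validate_config(config)
    return config


def config_hash(config: dict) -> str:
    """Stable hash of the canonicalised config (for run manifests)."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
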