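"""Run configuration and manifests for the command-line interface."""

from __future__ import annotations

import hashlib
import json

import numpy as np
import yaml

from . import __version__
from .index import IndexConfig
from .models import SmoothingConfig

SCHEMA_VERSION = 1

#: keys understood by run configs; anything else is rejected
KNOWN_KEYS = {
    "schema_version", "grid_size", "log_transform", "roi_method", "trim",
    "kind", "outcome_family", "n_basis_p_linear", "n_basis_p", "n_basis_q",
    "degree", "penalty_order", "q_margin", "lambda_min", "lambda_max",
    "n_lambda", "seed", "folds", "scenario", "n_subjects_per_group",
    "n_cells_per_subject", "outcome_kind", "n_replicates", "scenarios",
    "grid_sizes", "outcome_kinds", "n_subjects", "n_cells", "standardize",
}

DEFAULTS = {
    "schema_version": SCHEMA_VERSION,
    "grid_size": 19,
    "log_transform": True,
    "roi_method": "mean",
    "trim": 0,
    "kind": "nonlinear_nlQI",
    "outcome_family": None,
    "n_basis_p_linear": 8,
    "n_basis_p": 5,
    "n_basis_q": 5,
    "degree": 3,
    "penalty_order": 2,
    "q_margin": 0.05,
    "lambda_min": 1e-4,
    "lambda_max": 1e6,
    "n_lambda": 30,
    "seed": 0,
    "folds": 5,
    "standardize": True,
}


def load_config(path=None, **overrides) -> dict:
    """Merge defaults, an optional YAML file, and CLI overrides.

    Unknown keys are rejected before any computation runs.
    """
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a mapping")
        unknown = set(user) - KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if int(user.get("schema_version", SCHEMA_VERSION)) != SCHEMA_VERSION:
            raise ValueError("unsupported config schema version")
        cfg.update(user)
    for key, val in overrides.items():
        if val is None:
            continue
        if key not in KNOWN_KEYS:
            raise ValueError(f"unknown config key: {key}")
        cfg[key] = val
    return cfg


def index_config_from(cfg: dict) -> IndexConfig:
    grid = np.logspace(
        np.log10(cfg["lambda_min"]), np.log10(cfg["lambda_max"]), cfg["n_lambda"]
    )
    return IndexConfig(
        n_basis_p_linear=cfg["n_basis_p_linear"],
        n_basis_p=cfg["n_basis_p"],
        n_basis_q=cfg["n_basis_q"],
        degree=cfg["degree"],
        penalty_order=cfg["penalty_order"],
        q_margin=cfg["q_margin"],
        smoothing=SmoothingConfig(lambda_grid=grid, criterion="bic"),
    )


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, command: str, cfg: dict, inputs: dict, outputs: list) -> None:
    """Record everything needed to replay a CLI run (no timestamps, so
    identical runs yield identical manifests)."""
    manifest = {
        "command": command,
        "package_version": __version__,
        "config": {k: cfg[k] for k in sorted(cfg)},
        "config_hash": config_hash(cfg),
        "inputs": inputs,
        "outputs": outputs,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
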