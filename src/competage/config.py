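"""Flat namespaced run configuration with documented defaults.

One YAML file drives every subcommand; keys are ``module.key`` strings so
a screening campaign can share a single config across plates. Defaults
reproduce the package's documented behavior.
"""

from __future__ import annotations

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: dict = {
    "background.fallback_zero": False,
    "logratio.min_signal_factor": 1.0,
    "logratio.min_points": 3,
    "logratio.min_days": 2,
    "model.constraint": "sum_zero",
    "model.ci_level": 0.95,
    "kinetics.threshold": 0.35,
    "kinetics.delta_window": [0.05, 0.30],
    "kinetics.log_interpolation": False,
    "rescale.clamp": True,
    "rescale.eps": 1e-3,
    "tests.alpha_reference": 0.01,
    "tests.alpha_interaction": 0.05,
    "tests.equal_var": True,
    "qc.n_refs_grid": [1, 5, 10, 31],
    "qc.n_draws": 20,
}


def load_config(path: str | None) -> dict:
    """Load a YAML config and overlay it on the defaults."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg.update(user)
    if cfg["model.constraint"] != "sum_zero":
        raise ValueError("model.constraint supports only 'sum_zero'")
    return cfg


def merge_config(cfg: dict, overrides: dict) -> dict:
    out = dict(cfg)
    out.update({k: v for k, v in overrides.items() if v is not None})
    return out
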