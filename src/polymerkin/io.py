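"""Structured-text configuration for models and runs (YAML)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .models import ModelSpec, build_single_state_model, build_two_state_model
from .rates import RateSet

__all__ = ["rates_from_config", "model_from_config", "load_config", "dump_model_config"]

RATE_KEYS = ("k1", "k2", "k3", "k4", "km1", "km2", "km3", "km4", "k_trans")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def rates_from_config(cfg: dict) -> RateSet:
    block = cfg.get("rates", cfg)
    missing = [k for k in RATE_KEYS if k not in block and k != "k_trans"]
    if missing:
        raise ValueError(f"missing rate constants in config: {missing}")
    return RateSet(
        **{k: float(block.get(k, 0.0)) for k in RATE_KEYS},
        interpretation=cfg.get("interpretation", "custom"),
        provenance=cfg.get("provenance", {}),
    )


def model_from_config(cfg: dict) -> ModelSpec:
    """Build a model from ``{scheme, n_max, total_conc_uM, rates{...},
    interpretation, provenance}``."""
    rates = rates_from_config(cfg)
    scheme = cfg.get("scheme", "two_state")
    n_max = int(cfg["n_max"])
    total = float(cfg["total_conc_uM"])
    initial = cfg.get("initial_distribution_uM")
    initial = np.asarray(initial, dtype=float) if initial is not None else None
    if scheme == "single_state":
        return build_single_state_model(rates, n_max, total_conc=total, initial=initial)
    if scheme == "two_state":
        return build_two_state_model(rates, n_max, total_conc=total, initial=initial)
    raise ValueError(f"unknown scheme {scheme!r}")


def dump_model_config(model: ModelSpec, path) -> None:
    cfg = {
        "scheme": model.scheme,
        "n_max": model.n_max,
        "total_conc_uM": model.total_conc,
        "interpretation": model.rates.interpretation,
        "rates": {k: float(getattr(model.rates, k)) for k in RATE_KEYS},
        "provenance": dict(model.rates.provenance),
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
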