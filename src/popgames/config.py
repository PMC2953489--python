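"""Configuration files (YAML or JSON) describing a parameter set.

Two equivalent forms are accepted:

* shorthand -- no difference between in-group and out-group payoffs::

      B: -1
      C: 1
      f: 0.8

* full -- all eight payoff parameters::

      b1: -1
      c1: 2
      b2: -1
      c2: -2
      B1: -1
      C1: 2
      B2: -1
      C2: -2
      f: 0.5

Optional blocks apply transformations, in this order::

      punishment:
        gamma: 2.5        # or gamma1 / gamma2 per population
        beta: 12.5        # or beta1 / beta2
        cross: both       # or one_sided
      group_pressure: 0.5
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import yaml

from .games import (
    GameParams,
    PunishmentParams,
    apply_group_pressure_params,
    apply_punishment,
)

__all__ = ["ConfigError", "load_config", "build_params", "load_params"]

_SHORTHAND_KEYS = {"B", "C"}
_FULL_KEYS = {"b1", "c1", "b2", "c2", "B1", "C1", "B2", "C2"}
_TOP_KEYS = _SHORTHAND_KEYS | _FULL_KEYS | {"f", "punishment", "group_pressure"}


class ConfigError(ValueError):
    """Malformed configuration."""


def load_config(path) -> dict:
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg


def _number(cfg: dict, key: str, context: str = "config") -> float:
    if key not in cfg:
        raise ConfigError(f"missing required key {key!r} in {context}")
    v = cfg[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise ConfigError(f"key {key!r} must be a number, got {v!r}")
    return float(v)


def _punishment(block: dict) -> Tuple[PunishmentParams, str]:
    if not isinstance(block, dict):
        raise ConfigError("'punishment' must be a mapping")
    known = {"gamma", "beta", "gamma1", "gamma2", "beta1", "beta2", "cross"}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"unknown punishment keys: {sorted(unknown)}")

    def per_pop(name: str) -> Tuple[float, float]:
        if name in block:
            v = _number(block, name, "punishment")
            return v, v
        return (_number(block, name + "1", "punishment"),
                _number(block, name + "2", "punishment"))

    g1, g2 = per_pop("gamma")
    b1, b2 = per_pop("beta")
    cross = block.get("cross", "both")
    if cross not in ("both", "one_sided"):
        raise ConfigError(f"punishment cross mode must be 'both' or "
                          f"'one_sided', got {cross!r}")
    return PunishmentParams(gamma1=g1, gamma2=g2, beta1=b1, beta2=b2), cross


def build_params(cfg: dict) -> GameParams:
    """Resolve a config mapping into effective GameParams (punishment and
    group pressure applied)."""
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    has_short = bool(_SHORTHAND_KEYS & set(cfg))
    has_full = bool(_FULL_KEYS & set(cfg))
    if has_short and has_full:
        raise ConfigError("config mixes shorthand (B, C) and full "
                          "(b1..C2) parameter keys")
    if not has_short and not has_full:
        raise ConfigError("config must provide either shorthand keys "
                          "{B, C, f} or the eight full parameter keys plus f")
    f = _number(cfg, "f")
    if has_short:
        g = GameParams.shorthand(_number(cfg, "B"), _number(cfg, "C"), f)
    else:
        g = GameParams(**{k: _number(cfg, k) for k in sorted(_FULL_KEYS)}, f=f)
    if "punishment" in cfg:
        pp, cross = _punishment(cfg["punishment"])
        g = apply_punishment(g, pp, cross=cross)
    if "group_pressure" in cfg:
        g = apply_group_pressure_params(g, _number(cfg, "group_pressure"))
    return g


def load_params(path) -> GameParams:
    return build_params(load_config(path))
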