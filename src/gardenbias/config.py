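"""Run configuration: flat key-value documents -> a typed RunConfig."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .simulate import NOISE_MODES

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Raised for unknown, missing, or out-of-range configuration keys."""


@dataclass
class RunConfig:
    """Typed, defaulted pipeline configuration.

    Defaults mirror the study conditions: a 470-position garden with 22
    mortalities, 15 distance scenarios from 0.5 to 4 m, and 2000
    posterior draws.
    """

    layout_file: str | None = None
    n_positions: int = 470
    n_cols: int = 24
    dx: float = 1.0
    dy: float = 1.5
    n_dead: int = 22
    params_file: str | None = None   # JSON array of parameter sets
    spec_file: str | None = None     # GroupSpec JSON (synthetic draws)
    distances: list[float] = field(default_factory=lambda: list(np.linspace(0.5, 4.0, 15)))
    n_draws: int = 2000
    noise_mode: str = "independent"
    seed: int = 0
    out_dir: str = "gardenbias_out"
    band_levels: list[float] = field(default_factory=lambda: [0.68, 0.95])
    r_threshold: float = 0.99
    band_level: float = 0.68
    write_results: bool = True


def validate_config(raw: dict | str | None) -> RunConfig:
    """Build a RunConfig from a flat mapping (or YAML/JSON text).

    Unknown keys are rejected by name; values are type-coerced and
    range-checked. An empty document yields all defaults.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a flat key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")

    cfg = RunConfig(**raw)

    try:
        cfg.n_positions = int(cfg.n_positions)
        cfg.n_cols = int(cfg.n_cols)
        cfg.n_dead = int(cfg.n_dead)
        cfg.n_draws = int(cfg.n_draws)
        cfg.seed = int(cfg.seed)
        cfg.dx, cfg.dy = float(cfg.dx), float(cfg.dy)
        cfg.r_threshold = float(cfg.r_threshold)
        cfg.band_level = float(cfg.band_level)
        cfg.distances = [float(d) for d in cfg.distances]
        cfg.band_levels = [float(v) for v in cfg.band_levels]
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"could not coerce configuration value: {exc}") from exc

    if cfg.n_positions < 1 or cfg.n_cols < 1:
        raise ConfigError("n_positions and n_cols must be >= 1")
    if not 0 <= cfg.n_dead < cfg.n_positions:
        raise ConfigError("n_dead must satisfy 0 <= n_dead < n_positions")
    if cfg.dx <= 0 or cfg.dy <= 0:
        raise ConfigError("dx and dy must be positive")
    if cfg.n_draws < 1:
        raise ConfigError("n_draws must be >= 1")
    if cfg.noise_mode not in NOISE_MODES:
        raise ConfigError(f"noise_mode must be one of {NOISE_MODES}")
    if not cfg.distances or any(d <= 0 for d in cfg.distances):
        raise ConfigError("distances must be nonempty and positive")
    if sorted(cfg.distances) != cfg.distances:
        raise ConfigError("distances must be sorted ascending")
    if not 0 < cfg.r_threshold <= 1:
        raise ConfigError("r_threshold must lie in (0, 1]")
    for lv in cfg.band_levels + [cfg.band_level]:
        if not 0 < lv < 1:
            raise ConfigError("band levels must lie in (0, 1)")
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))
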