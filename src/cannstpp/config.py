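"""Run configuration: structured YAML in, validated records out.

A config file holds flat sections mirroring the package's parameter
records::

    model:      {tau_s, tau_1, tau_2, a, k, alpha, beta, r0, sigma_S, mu_Q, sigma_Q}
    stimulus:   {A, z0_initial, v_ext, mode, z0_after, t_jump}
    grid:       {n_points}
    integrator: {dt, method, t_max, record_every, convergence_tol}
    sweep:      {alpha_values, beta_values, v_ext_values, A_values, tau_2_values}
    output_dir: path
    log_level:  DEBUG | INFO | WARNING | ERROR

An empty file resolves to the study defaults.  Unknown keys are
rejected by name; constraint violations name the offending field.
Configs round-trip losslessly through :func:`save_config`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .model import ModelParams, RingGrid, StimulusSpec
from .protocols import SweepSpec
from .simulate import IntegratorConfig

logger = logging.getLogger("cannstpp")

_SECTIONS = ("model", "stimulus", "grid", "integrator", "sweep")
_TOP_KEYS = set(_SECTIONS) | {"output_dir", "log_level"}


class ConfigError(ValueError):
    """Malformed or invalid run configuration."""


@dataclass
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    grid: RingGrid = field(default_factory=RingGrid)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    sweep: SweepSpec = field(default_factory=SweepSpec)
    output_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "stimulus": self.stimulus.to_dict(),
            "grid": {"n_points": self.grid.n_points},
            "integrator": {
                "dt": self.integrator.dt,
                "method": self.integrator.method,
                "t_max": self.integrator.t_max,
                "record_every": self.integrator.record_every,
                "convergence_tol": self.integrator.convergence_tol,
            },
            "sweep": self.sweep.to_dict(),
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }


def _build_section(name: str, cls, data: dict):
    try:
        if cls is RingGrid:
            unknown = set(data) - {"n_points"}
            if unknown:
                raise ValueError(
                    f"unknown key(s) in grid section: {sorted(unknown)}"
                )
            return RingGrid(**data)
        if cls is IntegratorConfig:
            known = {"dt", "method", "t_max", "record_every", "convergence_tol"}
            unknown = set(data) - known
            if unknown:
                raise ValueError(
                    f"unknown key(s) in integrator section: {sorted(unknown)}"
                )
            return IntegratorConfig(**data)
        return cls.from_dict(data)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid '{name}' section: {err}") from err


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(
    path: Optional[str] = None, overrides: Optional[dict] = None
) -> RunConfig:
    """Defaults, file values and overrides merged in that order.

    ``overrides`` is a nested dict in the same shape as the file (e.g.
    ``{"model": {"alpha": 0.02}}``).  Every resolved value is echoed to
    the log at DEBUG level.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping: {path}")
        data = loaded
    if overrides:
        data = _deep_merge(data, overrides)

    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    for name in _SECTIONS:
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"'{name}' section must be a mapping")

    cfg = RunConfig(
        model=_build_section("model", ModelParams, data.get("model", {})),
        stimulus=_build_section("stimulus", StimulusSpec, data.get("stimulus", {})),
        grid=_build_section("grid", RingGrid, data.get("grid", {})),
        integrator=_build_section("integrator", IntegratorConfig,
                                  data.get("integrator", {})),
        sweep=_build_section("sweep", SweepSpec, data.get("sweep", {})),
        output_dir=str(data.get("output_dir", "results")),
        log_level=str(data.get("log_level", "INFO")),
    )
    for key, value in cfg.to_dict().items():
        logger.debug("config %s = %r", key, value)
    return cfg


def save_config(cfg: RunConfig, path: str) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
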