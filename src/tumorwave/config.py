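"""Run configuration: model, grid, analysis switches, and I/O settings.

Configs are YAML (JSON is a YAML subset and also accepted).  Validation is
strict: unknown keys raise, so a typo never silently falls back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .experiments import GridSpec
from .params import InvalidParameterError, ModelParams

__all__ = ["AnalysisConfig", "IOConfig", "RunConfig",
           "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unparsable or invalid configuration files."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Switches for analysis-stage behavior; defaults follow the model as
    printed (see the methods note for each switch's rationale)."""

    threshold: float = 0.01            # wave detection, frequency scale
    min_span: int = 500                # wave-width statistic cutoff
    covariate_sets: tuple[str, ...] = ("s,r,k,l", "s,c,k,l")
    fitness_weighting: str = "offspring"
    survival_exponent: str = "as_printed"
    size_log_arg: str = "product"
    at_least: bool = False             # waiting-time event definition
    log_scale_fits: bool = True        # quadratic wave fits on log abundance
    k_range: tuple[int, ...] = tuple(range(1, 7))
    l_range: tuple[int, ...] = tuple(range(1, 11))

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigError(f"threshold must be positive, got {self.threshold}")
        if self.min_span < 0:
            raise ConfigError(f"min_span must be >= 0, got {self.min_span}")
        if self.fitness_weighting not in ("offspring", "parent"):
            raise ConfigError(
                f"fitness_weighting must be 'offspring' or 'parent', "
                f"got {self.fitness_weighting!r}")
        if self.survival_exponent not in ("as_printed", "per_locus"):
            raise ConfigError(
                f"survival_exponent must be 'as_printed' or 'per_locus', "
                f"got {self.survival_exponent!r}")
        if self.size_log_arg not in ("product", "ratio"):
            raise ConfigError(
                f"size_log_arg must be 'product' or 'ratio', "
                f"got {self.size_log_arg!r}")
        for cs in self.covariate_sets:
            if cs not in ("s,r,k,l", "s,c,k,l"):
                raise ConfigError(f"unknown covariate set {cs!r}")
        object.__setattr__(self, "covariate_sets", tuple(self.covariate_sets))
        object.__setattr__(self, "k_range", tuple(self.k_range))
        object.__setattr__(self, "l_range", tuple(self.l_range))


@dataclass(frozen=True)
class IOConfig:
    out_dir: str = "tumorwave-out"
    keep_replicates: bool = False


@dataclass(frozen=True)
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    grid: GridSpec = field(default_factory=GridSpec)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    io: IOConfig = field(default_factory=IOConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        # derived fields are recomputed on load, not round-tripped
        d["model"].pop("r", None)
        d["model"].pop("alpha", None)
        return d


_SECTIONS = {"model": ModelParams, "grid": GridSpec,
             "analysis": AnalysisConfig, "io": IOConfig}


def _build_section(name: str, cls: type, data: dict[str, Any]) -> Any:
    import dataclasses

    known = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown keys in section '{name}': {sorted(unknown)} "
            f"(known: {sorted(known)})")
    try:
        return cls(**data)
    except (InvalidParameterError, ConfigError) as exc:
        raise ConfigError(f"section '{name}': {exc}") from exc


def config_from_dict(data: dict[str, Any] | None) -> RunConfig:
    """Build a validated RunConfig; missing sections take the study defaults."""
    data = dict(data or {})
    seed = data.pop("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    sections: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        payload = data.pop(name, {}) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        sections[name] = _build_section(name, cls, payload)
    if data:
        raise ConfigError(f"unknown top-level keys: {sorted(data)}")
    return RunConfig(seed=seed, **sections)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config; an empty file means all defaults."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
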