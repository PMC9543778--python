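"""Declarative pipeline configuration (YAML) with strict schema validation.

One document holds every stage's parameters: the generator
(:class:`~unfoldkit.simulate.SimulationConfig`), curve correction/filtering
(:class:`~unfoldkit.processing.ProcessingConfig`), event quantification
(:class:`~unfoldkit.events.EventConfig`), the landscape-fit settings, the
pulling-speed ladder, and the top-level seed from which all child seeds
derive.  Unknown keys are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from unfoldkit import presets
from unfoldkit.errors import ConfigError
from unfoldkit.events import EventConfig
from unfoldkit.processing import ProcessingConfig
from unfoldkit.simulate import SimulationConfig


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    """All tunables of the simulate -> filter -> quantify -> fit pipeline."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    events: EventConfig = field(default_factory=EventConfig)
    arrhenius_a: float = presets.ARRHENIUS_A_S
    effective_k: Optional[float] = None  # N/m, for the Fmp-vs-ln v alpha0 route
    speeds: Sequence[float] = presets.PULLING_SPEEDS_NM_S
    n_curves_per_speed: int = 50
    seed: int = 1

    def validate(self) -> None:
        self.simulation.validate()
        self.processing.validate()
        if self.arrhenius_a <= 0:
            raise ConfigError("arrhenius_a must be positive")
        if self.n_curves_per_speed < 1:
            raise ConfigError("n_curves_per_speed must be >= 1")
        if len(self.speeds) == 0 or any(v <= 0 for v in self.speeds):
            raise ConfigError("speeds must be positive and non-empty")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        top_allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_allowed
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in (
            ("simulation", SimulationConfig),
            ("processing", ProcessingConfig),
            ("events", EventConfig),
        ):
            if name in data:
                section = data.pop(name)
                if not isinstance(section, dict):
                    raise ConfigError(f"'{name}' must be a mapping")
                kwargs[name] = _build_section(section_cls, section, name)
        kwargs.update(data)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if data is not None and not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Short stable hash of the full configuration (for provenance)."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
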