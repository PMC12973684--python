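"""Structured pipeline configuration (YAML) and provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .io import ValidationError
from .signal import FilterSpec
from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "config_hash"]


@dataclass
class PipelineConfig:
    """All knobs of one reproducible run, loadable from a flat YAML tree."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    smooth_window: int = 9
    min_separation_s: float = 0.6
    min_prominence_z: float = 0.2
    window_len_s: float = 3.0
    statistic: str = "mean"
    threshold_z: float | None = None  # None: sweep selects it
    seed: int = 0
    n_recordings: int = 1

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValidationError("smooth.window must be odd and >= 1")
        if self.window_len_s <= 0:
            raise ValidationError("window_len_s must be > 0")
        self.filter.validate(self.simulate.fs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = SimulationConfig(**raw.pop("simulate", {}))
        filt = FilterSpec(**raw.pop("filter", {}))
        smooth = raw.pop("smooth", {})
        minima = raw.pop("minima", {})
        kwargs = dict(
            simulate=sim,
            filter=filt,
            smooth_window=smooth.get("window", 9),
            min_separation_s=minima.get("min_separation_s", 0.6),
            min_prominence_z=minima.get("min_prominence_z", 0.2),
        )
        allowed = {f.name for f in fields(cls)}
        for key, val in raw.items():
            if key not in allowed:
                raise ValidationError(f"unknown config key: {key}")
            kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter"] = asdict(self.filter)
        d["simulate"] = asdict(self.simulate)
        return d


def config_hash(config: PipelineConfig) -> str:
    """Short stable digest of the effective configuration, for provenance."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
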