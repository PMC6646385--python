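"""Run configuration: centralized defaults, YAML loading, fail-fast on
unknown keys, verbatim serialization into run outputs."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .instrument import InstrumentSpec


@dataclass
class RunConfig:
    """All tunable parameters of a reproducible analysis run."""

    instrument: InstrumentSpec = field(default_factory=InstrumentSpec)
    microns_per_pixel: float = 0.891      # brightfield calibration
    z_step: float = 7.0                   # confocal slice spacing, µm
    k_sigma: float = 3.0                  # peak detection threshold
    smooth_width: float = 15.0            # dip-detector smoothing, µm
    dip_ratio: float = 0.5                # dip threshold vs rim median
    erosion_iterations: int = 1
    min_count: int = 15                   # replication threshold per spheroid
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.z_step <= 0:
            raise ValueError("z_step must be > 0")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be > 0")
        if not 0 < self.dip_ratio < 1:
            raise ValueError("dip_ratio must lie in (0, 1)")
        if self.erosion_iterations < 0:
            raise ValueError("erosion_iterations must be >= 0")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "instrument" in data and isinstance(data["instrument"], dict):
            inst = data["instrument"]
            inst_known = {f.name for f in fields(InstrumentSpec)}
            bad = set(inst) - inst_known
            if bad:
                raise ValueError(f"unknown instrument keys: {sorted(bad)}")
            data["instrument"] = InstrumentSpec(**inst)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
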