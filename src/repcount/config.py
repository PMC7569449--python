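"""Run configuration: defaults, YAML loading, strict key checking."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .counters import CounterConfig
from .errors import ConfigError
from .preprocess import PreprocessConfig

__all__ = ["RunConfig"]


@dataclasses.dataclass
class RunConfig:
    """Every knob of a run, with defaults. Unknown config keys are rejected."""

    # signal IO
    fs: float = 50.0
    unit: str = "m/s2"
    time_unit: str = "s"
    # preprocessing
    gravity_window_s: float = 2.0
    sign_mode: str = "dynamic"
    # counters
    threshold_frac: float = 2.0 / 3.0
    refractory_s: float = 0.1
    alpha: float = 0.1
    band_hz: tuple[float, float] = (0.2, 5.0)
    round_mode: str = "nearest"
    # generator / benchmark
    n_subjects: int = 18
    duration_s: float = 30.0
    seed: int = 0
    # logging
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data, source=str(path))

    @classmethod
    def from_dict(cls, data: dict, source: str = "<dict>") -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{source}: unknown config key(s): {sorted(unknown)}")
        if "band_hz" in data:
            data = {**data, "band_hz": tuple(data["band_hz"])}
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        """Return a copy with non-None keyword overrides applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        unknown = set(updates) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return dataclasses.replace(self, **updates)

    def counter_config(self) -> CounterConfig:
        return CounterConfig(threshold_frac=self.threshold_frac,
                             refractory_s=self.refractory_s,
                             alpha=self.alpha, band_hz=tuple(self.band_hz),
                             round_mode=self.round_mode)

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(gravity_window_s=self.gravity_window_s,
                                sign_mode=self.sign_mode)
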