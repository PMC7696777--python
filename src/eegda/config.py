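"""Pipeline configuration: presets, validation, YAML round-trip.

Two dataset presets are built in, mirroring the two study designs the
pipeline targets:

* ``LGR`` — 14-channel consumer headset @ 128 Hz, Butterworth order 4 in
  [1, 63] Hz, alpha band (8-12 Hz), one-sided *increase* test;
* ``DM`` — 9-channel headset @ 256 Hz, order 5 in [1, 100] Hz, beta
  (13-29 Hz) and gamma (30-40 Hz) bands, one-sided *decrease* test.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .preprocess import FilterSpec

__all__ = ["PipelineConfig", "ConfigError", "PRESETS"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


PRESETS = {
    "LGR": {
        "fs": 128.0,
        "n_channels": 14,
        "filter": {"order": 4, "low": 1.0, "high": 63.0},
        "bands": {"alpha": [8.0, 12.0]},
        "alternative": "increase",
        "n_sessions": 19,
    },
    "DM": {
        "fs": 256.0,
        "n_channels": 9,
        "filter": {"order": 5, "low": 1.0, "high": 100.0},
        "bands": {"beta": [13.0, 29.0], "gamma": [30.0, 40.0]},
        "alternative": "decrease",
        "n_sessions": 3,
    },
}


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline."""

    preset: str = "LGR"
    fs: float = 128.0
    n_channels: int = 14
    filter: FilterSpec = field(default_factory=lambda: FilterSpec(4, 1.0, 63.0))
    bands: dict = field(default_factory=lambda: {"alpha": (8.0, 12.0)})
    # simulation
    n_sessions: int = 19
    duration: float = 60.0
    coupling: float = 0.8
    band_power_shift: float = 2.0
    effect_sessions: list = field(default_factory=list)
    coherent_triplet: tuple = (11, 12, 13)
    # selection
    nperseg: int | None = None
    n_surrogates: int = 100
    percentile: float = 95.0
    epoch_s: float = 4.0
    run_ica: bool = False
    # filter core
    taylor_order: int = 2
    ensemble_size: int | None = None
    # statistics
    alternative: str = "increase"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in (*PRESETS, "custom"):
            raise ConfigError(f"unknown preset {self.preset!r}")
        if isinstance(self.filter, dict):
            try:
                self.filter = FilterSpec(**self.filter)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid filter spec: {exc}") from exc
        try:
            self.filter.validate_for(self.fs)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        for name, band in self.bands.items():
            low, high = band
            if not (0 < low < high < self.fs / 2):
                raise ConfigError(
                    f"band {name!r} = {band} must satisfy 0 < low < high < fs/2"
                )
        if self.alternative not in ("increase", "decrease", "two-sided"):
            raise ConfigError(f"invalid alternative {self.alternative!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_sessions < 1:
            raise ConfigError("n_sessions must be >= 1")
        if self.n_surrogates < 20:
            raise ConfigError("n_surrogates must be >= 20")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "PipelineConfig":
        if name not in PRESETS:
            raise ConfigError(f"unknown preset {name!r}")
        base = PRESETS[name]
        kwargs = {
            "preset": name,
            "fs": base["fs"],
            "n_channels": base["n_channels"],
            "filter": FilterSpec(**base["filter"]),
            "bands": {k: tuple(v) for k, v in base["bands"].items()},
            "alternative": base["alternative"],
            "n_sessions": base["n_sessions"],
        }
        if base["n_channels"] == 9:
            kwargs["coherent_triplet"] = (3, 6, 7)
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(open(path)) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        preset = raw.pop("preset", "custom")
        if preset in PRESETS:
            try:
                return cls.from_preset(preset, **raw)
            except TypeError as exc:
                raise ConfigError(f"unknown config key: {exc}") from exc
        raw["preset"] = preset
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"unknown config key: {exc}") from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
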