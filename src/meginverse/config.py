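"""Structured run configuration with validated defaults.

The defaults describe a desk-scale experiment that runs end to end on one
CPU: a 32-sensor helmet, an 8-cm source sphere simulated on a 15-mm grid and
reconstructed on a 28-mm grid, 5,000 training examples.  The corresponding
full-scale values used for headline results in the field are S=127 sensors,
5-mm simulation / 15-mm reconstruction grids and 2e5 training examples; every
field here accepts those values unchanged.

Configs are YAML files mirroring the section layout below; unknown keys are
rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidConfigError

__all__ = [
    "GeometryConfig",
    "SignalConfig",
    "DatasetConfig",
    "NetworkSection",
    "TrainingSection",
    "BenchmarkConfig",
    "RunConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class GeometryConfig:
    n_sensors: int = 32  # full scale: 127
    sensor_radius: float = 0.12  # meters
    cap_fraction: float = 0.6
    source_radius: float = 0.08  # meters
    forward_spacing: float = 0.015  # meters; full scale: 0.005
    inverse_spacing: float = 0.033  # meters (57-node output grid); full scale: 0.015
    orientation_seed: int = 0

    def validate(self) -> None:
        for name in ("sensor_radius", "source_radius", "forward_spacing", "inverse_spacing"):
            if not getattr(self, name) > 0:
                raise InvalidConfigError(f"geometry.{name} must be positive")
        if self.n_sensors < 1:
            raise InvalidConfigError("geometry.n_sensors must be positive")
        if self.source_radius >= self.sensor_radius:
            raise InvalidConfigError(
                "geometry.source_radius must be smaller than sensor_radius"
            )
        if not 0 < self.cap_fraction <= 1:
            raise InvalidConfigError("geometry.cap_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SignalConfig:
    t0_range: tuple[float, float] = (0.05, 0.3)  # s
    omega_range: tuple[float, float] = (0.04, 0.12)  # s
    f0_range: tuple[float, float] = (8.0, 14.0)  # Hz (alpha band)
    phi_range: tuple[float, float] = (0.0, 2.0 * np.pi)  # rad
    duration: float = 0.4  # s
    fs: float = 1000.0  # Hz
    extended_volume_range: tuple[float, float] = (14.0, 44.0)  # cm^3

    def validate(self) -> None:
        for name in ("t0_range", "omega_range", "f0_range", "phi_range",
                     "extended_volume_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidConfigError(f"signal.{name} is inverted: [{lo}, {hi}]")
        if not (self.duration > 0 and self.fs > 0):
            raise InvalidConfigError("signal.duration and signal.fs must be positive")

    @property
    def param_ranges(self) -> dict[str, tuple[float, float]]:
        return {
            "t0": tuple(self.t0_range),
            "omega": tuple(self.omega_range),
            "f0": tuple(self.f0_range),
            "phi": tuple(self.phi_range),
        }


@dataclass(frozen=True)
class DatasetConfig:
    n_examples: int = 5000  # full scale: 200000
    focal_fraction: float = 0.5
    snr_range: tuple[float, float] = (0.0, 30.0)  # dB
    window_length: int = 21
    focal_group_choices: tuple[int, ...] = (1, 2, 3)
    extended_group_choices: tuple[int, ...] = (1, 2)

    def validate(self) -> None:
        if self.n_examples < 1:
            raise InvalidConfigError("dataset.n_examples must be positive")
        if not 0 <= self.focal_fraction <= 1:
            raise InvalidConfigError("dataset.focal_fraction must be in [0, 1]")
        if self.snr_range[0] > self.snr_range[1]:
            raise InvalidConfigError(
                f"dataset.snr_range is inverted: {list(self.snr_range)}"
            )
        if self.window_length % 2 != 1:
            raise InvalidConfigError("dataset.window_length must be odd")


@dataclass(frozen=True)
class NetworkSection:
    conv_feature_schedule: tuple[int, ...] = (16, 32, 64, 128)
    conv_kernel_schedule: tuple[int, ...] | None = None  # auto from window length
    fc_layers: int = 6
    fc_width: int = 500

    def validate(self) -> None:
        if self.fc_layers < 1 or self.fc_width < 1:
            raise InvalidConfigError("network.fc_layers/fc_width must be positive")
        if not self.conv_feature_schedule:
            raise InvalidConfigError("network.conv_feature_schedule must be non-empty")


@dataclass(frozen=True)
class TrainingSection:
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 30
    validation_fraction: float = 0.1

    def validate(self) -> None:
        if not self.learning_rate > 0:
            raise InvalidConfigError("training.learning_rate must be > 0")
        if self.batch_size < 1:
            raise InvalidConfigError("training.batch_size must be >= 1")
        if self.epochs < 1:
            raise InvalidConfigError("training.epochs must be >= 1")


@dataclass(frozen=True)
class BenchmarkConfig:
    methods: tuple[str, ...] = ("deep", "lcmv", "mne", "eloreta", "rv")
    # each entry: (scenario kind, number of active groups)
    scenarios: tuple[tuple[str, int], ...] = (
        ("single_focal", 1),
        ("multi_focal", 2),
        ("multi_focal", 3),
        ("extended", 1),
        ("extended", 2),
    )
    test_snrs_db: tuple[float, ...] = (30.0, 10.0)  # full scale adds 20, 0
    n_test_cases: int = 20  # full scale: 100
    seed: int = 0

    def validate(self) -> None:
        known = {"deep", "lcmv", "mne", "eloreta", "rv"}
        unknown = set(self.methods) - known
        if unknown:
            raise InvalidConfigError(f"benchmark.methods unknown: {sorted(unknown)}")
        for kind, n in self.scenarios:
            if kind not in ("single_focal", "multi_focal", "extended"):
                raise InvalidConfigError(f"benchmark.scenarios: unknown kind {kind!r}")
            if n < 1:
                raise InvalidConfigError("benchmark.scenarios: n_groups must be >= 1")
        if self.n_test_cases < 1:
            raise InvalidConfigError("benchmark.n_test_cases must be >= 1")


_SECTIONS = {
    "geometry": GeometryConfig,
    "signal": SignalConfig,
    "dataset": DatasetConfig,
    "network": NetworkSection,
    "training": TrainingSection,
    "benchmark": BenchmarkConfig,
}


@dataclass(frozen=True)
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    network: NetworkSection = field(default_factory=NetworkSection)
    training: TrainingSection = field(default_factory=TrainingSection)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)

    def validate(self) -> "RunConfig":
        for name in _SECTIONS:
            getattr(self, name).validate()
        half = (self.dataset.window_length - 1) / 2
        n_time = int(round(self.signal.duration * self.signal.fs))
        if self.dataset.window_length > n_time:
            raise InvalidConfigError(
                f"dataset.window_length {self.dataset.window_length} exceeds the "
                f"trial length {n_time}; half-window {half}"
            )
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def _coerce(section_cls, raw: dict, section_name: str):
    known = {f.name for f in fields(section_cls)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidConfigError(
            f"unknown key(s) in section '{section_name}': {sorted(unknown)}"
        )
    coerced = {}
    for f in fields(section_cls):
        if f.name not in raw:
            continue
        v = raw[f.name]
        if isinstance(v, list):
            v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
        coerced[f.name] = v
    return section_cls(**coerced)


def config_from_dict(data: dict | None) -> RunConfig:
    data = data or {}
    if not isinstance(data, dict):
        raise InvalidConfigError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise InvalidConfigError(f"unknown config section(s): {sorted(unknown)}")
    sections = {
        name: _coerce(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(**sections).validate()


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML config file; missing keys fall back to defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    data = yaml.safe_load(path.read_text())
    return config_from_dict(data)


def save_config(path: str | Path, config: RunConfig) -> None:
    """Write a fully resolved config as YAML (round-trips via load_config)."""

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    Path(path).write_text(yaml.safe_dump(clean(config.to_dict()), sort_keys=False))
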