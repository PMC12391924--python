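"""Ground-truth source activity and noisy sensor recordings.

Every active source emits a Gaussian-damped sinusoid

    g(t) = sin(2 pi f0 t + phi) * exp(-(t - t0)^2 / omega^2)

whose four parameters are drawn uniformly from configurable ranges; the
defaults put f0 in the alpha band (8-14 Hz) with the envelope center t0 in
[0.05, 0.3] s and damping omega in [0.04, 0.12] s.  Trials last 0.4 s at
1 kHz (400 samples).

Activations are either *focal* (1-3 isolated dipoles, independent signals) or
*extended* (1-2 lattice-connected sub-volumes of 14-44 cm^3 sharing one
signal realization per region).  Sensor data follow the linear model
``M = L Q + N`` with additive white Gaussian noise at a requested sensor-space
SNR, defined as the decibel ratio of mean clean signal power (over all
sensors and samples) to noise variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import (
    InvalidConfigError,
    InvalidParameterError,
    InputContractError,
    ScenarioGenerationError,
    UndefinedSNRError,
)
from .forward import Leadfield
from .geometry import SourceSpace

__all__ = [
    "DEFAULT_PARAM_RANGES",
    "DEFAULT_DURATION",
    "DEFAULT_FS",
    "SignalParams",
    "ActiveGroup",
    "Scenario",
    "SourceActivity",
    "SensorRecording",
    "default_time_axis",
    "sample_signal_params",
    "gaussian_damped_sine",
    "make_scenario",
    "render_source_activity",
    "simulate_recording",
    "scenario_to_json",
    "scenario_from_json",
]

#: per-parameter uniform ranges: t0 [s], omega [s], f0 [Hz], phi [rad]
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "t0": (0.05, 0.3),
    "omega": (0.04, 0.12),
    "f0": (8.0, 14.0),
    "phi": (0.0, 2.0 * np.pi),
}

DEFAULT_DURATION = 0.4  # seconds
DEFAULT_FS = 1000.0  # Hz

#: extended-region volume range [cm^3]
DEFAULT_EXTENDED_VOLUME_RANGE = (14.0, 44.0)


def default_time_axis(duration: float = DEFAULT_DURATION, fs: float = DEFAULT_FS) -> np.ndarray:
    """Trial time axis: ``duration`` seconds sampled at ``fs`` Hz."""
    return np.arange(int(round(duration * fs))) / fs


@dataclass(frozen=True)
class SignalParams:
    """Parameters of one Gaussian-damped sine: envelope center/width, carrier."""

    t0: float
    omega: float
    f0: float
    phi: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise InvalidParameterError(f"omega must be positive, got {self.omega}")


@dataclass(frozen=True)
class ActiveGroup:
    """A set of simultaneously active dipoles sharing one signal realization."""

    indices: tuple[int, ...]
    params: SignalParams


@dataclass(frozen=True)
class Scenario:
    """Ground-truth activation layout for one trial."""

    kind: str  # single_focal | multi_focal | extended
    groups: tuple[ActiveGroup, ...]
    time_axis: np.ndarray
    fs: float
    n_sources: int
    voxel_volume: float  # cm^3

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for g in self.groups:
            if seen.intersection(g.indices):
                raise ScenarioGenerationError("active groups must be disjoint")
            seen.update(g.indices)

    @property
    def active_indices(self) -> np.ndarray:
        return np.array(sorted(i for g in self.groups for i in g.indices), dtype=int)


@dataclass(frozen=True)
class SourceActivity:
    """D x T matrix of dipole amplitudes [A*m] (ground truth or estimate)."""

    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", a)
        if a.ndim != 2:
            raise InputContractError("amplitudes must be a D x T matrix")

    @property
    def n_sources(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.amplitudes.shape[1]


@dataclass(frozen=True)
class SensorRecording:
    """S x T sensor matrix [tesla] with its noise annotation.

    ``clean`` and ``noise`` retain the two parts of ``samples`` so realized
    SNR can be audited; ``snr_db`` is ``inf`` for noiseless data.
    """

    samples: np.ndarray
    snr_db: float
    noise_seed: int = -1
    clean: np.ndarray | None = field(default=None, repr=False)
    noise: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 2:
            raise InputContractError("samples must be an S x T matrix")
        if not np.all(np.isfinite(s)):
            raise InputContractError("sensor samples must be finite")

    @property
    def n_sensors(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def sample_signal_params(
    rng: np.random.Generator,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> SignalParams:
    """Draw one parameter set, each parameter independent uniform on its range."""
    ranges = dict(DEFAULT_PARAM_RANGES if ranges is None else ranges)
    out = {}
    for name in ("t0", "omega", "f0", "phi"):
        lo, hi = ranges[name]
        if lo > hi:
            raise InvalidConfigError(f"inverted range for {name}: [{lo}, {hi}]")
        out[name] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return SignalParams(**out)


def gaussian_damped_sine(params: SignalParams, time_axis: np.ndarray) -> np.ndarray:
    """Evaluate g(t) = sin(2 pi f0 t + phi) exp(-(t - t0)^2 / omega^2)."""
    t = np.asarray(time_axis, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InvalidParameterError("time axis must be strictly increasing")
    envelope = np.exp(-((t - params.t0) ** 2) / params.omega**2)
    return np.sin(2.0 * np.pi * params.f0 * t + params.phi) * envelope


def _grow_region(
    seed_voxel: int,
    n_target: int,
    neighbors: list[list[int]],
    blocked: set[int],
    rng: np.random.Generator,
) -> list[int] | None:
    """Grow a connected region by uniform random frontier accretion."""
    region = [seed_voxel]
    members = {seed_voxel}
    frontier = [n for n in neighbors[seed_voxel] if n not in blocked]
    while len(region) < n_target:
        frontier = [v for v in frontier if v not in members]
        if not frontier:
            return None
        pick = frontier.pop(int(rng.integers(len(frontier))))
        region.append(pick)
        members.add(pick)
        frontier.extend(
            n for n in neighbors[pick] if n not in members and n not in blocked
        )
    return region


def _neighbor_lists(source_space: SourceSpace) -> list[list[int]]:
    pairs = source_space.neighbor_pairs()
    out: list[list[int]] = [[] for _ in range(source_space.count)]
    for i, j in pairs:
        out[i].append(j)
        out[j].append(i)
    return out


def make_scenario(
    kind: str,
    n_groups: int,
    source_space: SourceSpace,
    rng: np.random.Generator,
    param_ranges: dict[str, tuple[float, float]] | None = None,
    extended_volume_range: tuple[float, float] = DEFAULT_EXTENDED_VOLUME_RANGE,
    duration: float = DEFAULT_DURATION,
    fs: float = DEFAULT_FS,
    candidate_indices: np.ndarray | None = None,
    max_retries: int = 50,
) -> Scenario:
    """Draw one activation scenario.

    Focal kinds place ``n_groups`` distinct dipoles, each with its own signal
    parameters.  The extended kind grows each group from a random seed voxel
    by uniform 6-neighbor accretion until a volume drawn uniformly from
    ``extended_volume_range`` is covered; all dipoles in a group share one
    parameter set.  ``candidate_indices`` optionally restricts where focal
    dipoles / seed voxels may be placed; by default a dipole at the exact
    origin is excluded (it is silent in a spherically symmetric conductor).
    """
    if kind not in ("single_focal", "multi_focal", "extended"):
        raise InvalidConfigError(f"unknown scenario kind {kind!r}")
    if kind == "single_focal" and n_groups != 1:
        raise InvalidConfigError("single_focal requires n_groups == 1")
    if n_groups < 1:
        raise InvalidConfigError("n_groups must be >= 1")
    time_axis = default_time_axis(duration, fs)
    if candidate_indices is None:
        off_origin = np.linalg.norm(source_space.positions, axis=1) > 0
        candidates = np.flatnonzero(off_origin)
    else:
        candidates = np.asarray(candidate_indices, dtype=int)
    vv = source_space.voxel_volume
    groups: list[ActiveGroup] = []

    if kind in ("single_focal", "multi_focal"):
        if n_groups > candidates.size:
            raise ScenarioGenerationError("more focal groups than candidate dipoles")
        chosen = rng.choice(candidates, size=n_groups, replace=False)
        for idx in np.atleast_1d(chosen):
            groups.append(
                ActiveGroup(
                    indices=(int(idx),),
                    params=sample_signal_params(rng, param_ranges),
                )
            )
    else:
        lo, hi = extended_volume_range
        n_min = int(np.ceil(lo / vv))
        n_max = int(np.floor(hi / vv))
        if n_max < max(n_min, 1):
            raise ScenarioGenerationError(
                f"voxel volume {vv:.3g} cm^3 cannot tile a region in "
                f"[{lo}, {hi}] cm^3"
            )
        neighbors = _neighbor_lists(source_space)
        used: set[int] = set()
        for _ in range(n_groups):
            target_volume = rng.uniform(lo, hi)
            n_target = int(np.clip(round(target_volume / vv), n_min, n_max))
            region = None
            for _ in range(max_retries):
                free = [int(c) for c in candidates if c not in used]
                if not free:
                    break
                seed = free[int(rng.integers(len(free)))]
                region = _grow_region(seed, n_target, neighbors, used, rng)
                if region is not None:
                    break
            if region is None:
                raise ScenarioGenerationError(
                    f"could not grow a {n_target}-voxel region after "
                    f"{max_retries} retries"
                )
            used.update(region)
            groups.append(
                ActiveGroup(
                    indices=tuple(int(i) for i in sorted(region)),
                    params=sample_signal_params(rng, param_ranges),
                )
            )

    return Scenario(
        kind=kind,
        groups=tuple(groups),
        time_axis=time_axis,
        fs=fs,
        n_sources=source_space.count,
        voxel_volume=vv,
    )


def render_source_activity(scenario: Scenario) -> SourceActivity:
    """Evaluate every group's signal onto its dipole rows; other rows zero."""
    amplitudes = np.zeros((scenario.n_sources, scenario.time_axis.size))
    for group in scenario.groups:
        g = gaussian_damped_sine(group.params, scenario.time_axis)
        amplitudes[list(group.indices), :] = g
    return SourceActivity(amplitudes=amplitudes)


def simulate_recording(
    activity: SourceActivity,
    leadfield: Leadfield,
    snr_db: float,
    rng: np.random.Generator | int | None = None,
) -> SensorRecording:
    """Forward-project activity and add white Gaussian sensor noise.

    Noise variance is set from the *global* clean signal power:
    ``10 log10(mean(clean^2) / var) = snr_db``.  Pass ``snr_db=inf`` for a
    noiseless recording.  ``rng`` may be a Generator or an integer seed (the
    seed is then recorded on the output for exact replay).
    """
    if activity.n_sources != leadfield.n_sources:
        raise InputContractError(
            f"activity has {activity.n_sources} sources, leadfield expects "
            f"{leadfield.n_sources}"
        )
    clean = leadfield.gain @ activity.amplitudes
    if np.isinf(snr_db):
        return SensorRecording(
            samples=clean, snr_db=np.inf, clean=clean,
            noise=np.zeros_like(clean),
        )
    clean_power = float(np.mean(clean**2))
    if clean_power == 0.0:
        raise UndefinedSNRError("all-zero clean signal with finite SNR requested")
    noise_seed = -1
    if rng is None or isinstance(rng, (int, np.integer)):
        noise_seed = int(rng) if rng is not None else -1
        rng = np.random.default_rng(None if noise_seed < 0 else noise_seed)
    noise_std = np.sqrt(clean_power / 10.0 ** (snr_db / 10.0))
    noise = rng.normal(0.0, noise_std, size=clean.shape)
    return SensorRecording(
        samples=clean + noise, snr_db=float(snr_db), noise_seed=noise_seed,
        clean=clean, noise=noise,
    )


def scenario_to_json(scenario: Scenario) -> str:
    """Structured-text export of active indices and signal parameters."""
    payload = {
        "kind": scenario.kind,
        "fs": scenario.fs,
        "n_samples": int(scenario.time_axis.size),
        "n_sources": scenario.n_sources,
        "voxel_volume_cm3": scenario.voxel_volume,
        "groups": [
            {"indices": list(g.indices), "params": asdict(g.params)}
            for g in scenario.groups
        ],
    }
    return json.dumps(payload, indent=2)


def scenario_from_json(text: str) -> Scenario:
    payload = json.loads(text)
    groups = tuple(
        ActiveGroup(indices=tuple(g["indices"]), params=SignalParams(**g["params"]))
        for g in payload["groups"]
    )
    fs = float(payload["fs"])
    return Scenario(
        kind=payload["kind"],
        groups=groups,
        time_axis=np.arange(int(payload["n_samples"])) / fs,
        fs=fs,
        n_sources=int(payload["n_sources"]),
        voxel_volume=float(payload["voxel_volume_cm3"]),
    )
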