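"""Windowed training examples for the source-reconstruction network.

Each example pairs an S x W sensor window (W odd, default 21 samples) with the
D-vector of dipole amplitudes at the window's center sample.  Trials are drawn
half focal / half extended by default, with sensor noise at an SNR sampled
uniformly from [0, 30] dB per example.

When the network's output grid is coarser than the simulation grid (the usual
setting: simulate finely, reconstruct coarsely), each coarse node's target is
taken from the fine dipoles nearest to it (see :func:`project_activity` for
the two conventions offered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidConfigError
from .forward import Leadfield
from .geometry import SourceSpace
from .signals import (
    DEFAULT_EXTENDED_VOLUME_RANGE,
    DEFAULT_PARAM_RANGES,
    SourceActivity,
    make_scenario,
    render_source_activity,
    simulate_recording,
)

__all__ = [
    "TrainingExample",
    "TrainingSet",
    "project_activity",
    "build_training_set",
    "dataset_to_bundle",
    "dataset_from_bundle",
]


@dataclass(frozen=True)
class TrainingExample:
    """One (sensor window, center-sample source amplitudes) pair."""

    window: np.ndarray  # (S, W)
    target: np.ndarray  # (D,)
    center_index: int
    snr_db: float
    kind: str


@dataclass
class TrainingSet:
    """Stacked training examples plus provenance metadata."""

    windows: np.ndarray  # (N, S, W)
    targets: np.ndarray  # (N, D)
    centers: np.ndarray  # (N,)
    snrs: np.ndarray  # (N,)
    kinds: list[str]
    meta: dict

    def __len__(self) -> int:
        return self.windows.shape[0]

    def __getitem__(self, i: int) -> TrainingExample:
        return TrainingExample(
            window=self.windows[i],
            target=self.targets[i],
            center_index=int(self.centers[i]),
            snr_db=float(self.snrs[i]),
            kind=self.kinds[i],
        )


def project_activity(
    activity: SourceActivity,
    fine_space: SourceSpace,
    coarse_space: SourceSpace,
    mode: str = "dominant",
) -> SourceActivity:
    """Map fine-grid dipole activity onto the nearest coarse-grid nodes.

    Two conventions:

    * ``"dominant"`` (default): each coarse node carries the trace of the
      highest-energy fine dipole mapped to it.  This keeps focal and extended
      activations on the same unit-peak amplitude scale — the node amplitude
      reads as "amplitude of activity in this region".
    * ``"sum"``: amplitudes accumulate, so the node reads as the total dipole
      moment of its cell (linear in the activity, conserves total moment, but
      scales with the number of active dipoles per cell).
    """
    tree = cKDTree(coarse_space.positions)
    _, nearest = tree.query(fine_space.positions)
    out = np.zeros((coarse_space.count, activity.n_samples))
    if mode == "sum":
        np.add.at(out, nearest, activity.amplitudes)
    elif mode == "dominant":
        energies = np.einsum("dt,dt->d", activity.amplitudes, activity.amplitudes)
        best_energy = np.zeros(coarse_space.count)
        best_row = np.full(coarse_space.count, -1)
        for i, node in enumerate(nearest):
            if energies[i] > best_energy[node]:
                best_energy[node] = energies[i]
                best_row[node] = i
        active = best_row >= 0
        out[active] = activity.amplitudes[best_row[active]]
    else:
        raise InvalidConfigError(f"unknown projection mode {mode!r}")
    return SourceActivity(amplitudes=out)


def build_training_set(
    n_examples: int,
    focal_fraction: float,
    window_length: int,
    snr_range: tuple[float, float],
    source_space: SourceSpace,
    leadfield: Leadfield,
    rng: np.random.Generator,
    output_space: SourceSpace | None = None,
    focal_group_choices: tuple[int, ...] = (1, 2, 3),
    extended_group_choices: tuple[int, ...] = (1, 2),
    param_ranges: dict | None = None,
    extended_volume_range: tuple[float, float] = DEFAULT_EXTENDED_VOLUME_RANGE,
    duration: float = 0.4,
    fs: float = 1000.0,
    keep_trials: bool = False,
    projection: str = "dominant",
) -> TrainingSet:
    """Generate windowed training examples from fresh random trials.

    Exactly ``round(n_examples * focal_fraction)`` examples are focal, the
    rest extended; example order is shuffled.  Each example uses a fresh
    scenario, one noise realization at an SNR uniform on ``snr_range``, and a
    window center drawn uniformly from positions where the full window fits.

    With ``keep_trials=True`` the per-example (scenario, activity) pairs are
    retained in ``meta["trials"]`` for auditing; off by default to keep
    memory flat.
    """
    if window_length % 2 != 1:
        raise InvalidConfigError(f"window length must be odd, got {window_length}")
    if not 0 <= focal_fraction <= 1:
        raise InvalidConfigError("focal_fraction must be in [0, 1]")
    if snr_range[0] > snr_range[1]:
        raise InvalidConfigError(f"inverted SNR range {snr_range}")
    n_time = int(round(duration * fs))
    if window_length > n_time:
        raise InvalidConfigError(
            f"window length {window_length} exceeds trial length {n_time}"
        )
    half = (window_length - 1) // 2
    n_focal = int(round(n_examples * focal_fraction))
    is_focal = np.zeros(n_examples, dtype=bool)
    is_focal[:n_focal] = True
    rng.shuffle(is_focal)

    if param_ranges is None:
        param_ranges = dict(DEFAULT_PARAM_RANGES)
    project = output_space is not None and output_space is not source_space
    n_out = output_space.count if project else source_space.count

    windows = np.empty((n_examples, leadfield.n_sensors, window_length))
    targets = np.empty((n_examples, n_out))
    centers = np.empty(n_examples, dtype=int)
    snrs = np.empty(n_examples)
    kinds: list[str] = []
    trials: list = []

    for i in range(n_examples):
        if is_focal[i]:
            n_groups = int(rng.choice(focal_group_choices))
            kind = "single_focal" if n_groups == 1 else "multi_focal"
        else:
            n_groups = int(rng.choice(extended_group_choices))
            kind = "extended"
        scenario = make_scenario(
            kind,
            n_groups,
            source_space,
            rng,
            param_ranges=param_ranges,
            extended_volume_range=extended_volume_range,
            duration=duration,
            fs=fs,
        )
        activity = render_source_activity(scenario)
        snr_db = float(rng.uniform(*snr_range))
        recording = simulate_recording(activity, leadfield, snr_db, rng)
        center = int(rng.integers(half, n_time - half))
        windows[i] = recording.samples[:, center - half : center + half + 1]
        target_activity = (
            project_activity(activity, source_space, output_space, mode=projection)
            if project
            else activity
        )
        targets[i] = target_activity.amplitudes[:, center]
        centers[i] = center
        snrs[i] = snr_db
        kinds.append(kind)
        if keep_trials:
            trials.append((scenario, activity))

    return TrainingSet(
        windows=windows,
        targets=targets,
        centers=centers,
        snrs=snrs,
        kinds=kinds,
        meta={
            "n_examples": n_examples,
            "focal_fraction": focal_fraction,
            "window_length": window_length,
            "snr_range": list(snr_range),
            "duration": duration,
            "fs": fs,
            "projected": project,
            "projection": projection if project else None,
            **({"trials": trials} if keep_trials else {}),
        },
    )


def dataset_to_bundle(ts: TrainingSet):
    """Pack a training set into an :class:`~meginverse.bundle.ArrayBundle`."""
    from .bundle import ArrayBundle

    kind_codes = {"single_focal": 0, "multi_focal": 1, "extended": 2}
    return ArrayBundle(
        arrays={
            "windows": ts.windows,
            "targets": ts.targets,
            "centers": ts.centers,
            "snrs": ts.snrs,
            "kinds": np.array([kind_codes[k] for k in ts.kinds], dtype=np.int8),
        },
        meta={"kind": "training_set",
              **{k: v for k, v in ts.meta.items() if k != "trials"}},
    )


def dataset_from_bundle(bundle) -> TrainingSet:
    codes = {0: "single_focal", 1: "multi_focal", 2: "extended"}
    meta = {k: v for k, v in bundle.meta.items() if k != "kind"}
    return TrainingSet(
        windows=bundle.arrays["windows"],
        targets=bundle.arrays["targets"],
        centers=bundle.arrays["centers"],
        snrs=bundle.arrays["snrs"],
        kinds=[codes[int(c)] for c in bundle.arrays["kinds"]],
        meta=meta,
    )
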