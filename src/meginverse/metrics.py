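"""Localization and reconstruction quality metrics.

A dipole counts as *active* when its time-integrated energy exceeds 50% of
the maximum dipole energy (threshold configurable).  On active sets the
package reports:

* DLE — mean, over true sources, of the distance to the nearest estimated
  active source, in mm (asymmetric by design).
* AV — active volume: number of active voxels times the voxel volume, cm^3.
* IoU — intersection over union of true and estimated active voxel sets, %.
* NRMSE — RMS difference between energy-normalized signal *envelopes*
  (analytic-signal magnitude), scale-free.

The deep/cortical split ranks focal test cases by the distance of their
active source from the "deep point", the grid dipole with the greatest mean
distance from the sensors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .errors import InputContractError, UndefinedMetricError
from .geometry import SensorArray, SourceSpace

__all__ = [
    "ActiveSet",
    "MetricsReport",
    "active_set",
    "dle",
    "active_volume",
    "nrmse",
    "iou",
    "deep_point",
    "depth_split",
]


@dataclass(frozen=True)
class ActiveSet:
    """Dipoles whose energy clears the relative threshold."""

    indices: frozenset[int]
    energies: np.ndarray
    threshold_fraction: float = 0.5


@dataclass(frozen=True)
class MetricsReport:
    """One trial's metric values plus scenario metadata."""

    dle_mm: float
    active_volume_cm3: float
    nrmse: float | None = None
    iou_percent: float | None = None
    meta: dict = field(default_factory=dict)


def active_set(
    activity_or_energies: np.ndarray, threshold_fraction: float = 0.5
) -> ActiveSet:
    """Threshold dipole energies at a fraction of the maximum.

    Accepts a D x T amplitude matrix (energies are summed squared amplitudes
    over time) or a precomputed D-vector of energies.
    """
    arr = np.asarray(
        getattr(activity_or_energies, "amplitudes", activity_or_energies),
        dtype=float,
    )
    if arr.ndim == 2:
        energies = np.einsum("dt,dt->d", arr, arr)
    elif arr.ndim == 1:
        energies = arr
    else:
        raise InputContractError("expected a D-vector of energies or a D x T matrix")
    emax = energies.max(initial=0.0)
    if emax == 0.0:
        warnings.warn("all-zero activity: empty active set", stacklevel=2)
        return ActiveSet(
            indices=frozenset(), energies=energies,
            threshold_fraction=threshold_fraction,
        )
    members = np.flatnonzero(energies > threshold_fraction * emax)
    return ActiveSet(
        indices=frozenset(int(i) for i in members),
        energies=energies,
        threshold_fraction=threshold_fraction,
    )


def dle(true_positions: np.ndarray, est_positions: np.ndarray) -> float:
    """Distance of localization error in mm.

    Mean over true source positions of the minimum Euclidean distance to any
    estimated active source position (positions in meters).  An empty
    estimate yields ``inf`` so silent failures remain visible.
    """
    true_pos = np.atleast_2d(np.asarray(true_positions, dtype=float))
    if true_pos.size == 0:
        raise InputContractError("true position set must be non-empty")
    est_pos = np.atleast_2d(np.asarray(est_positions, dtype=float))
    if est_pos.size == 0:
        warnings.warn("empty estimated active set: DLE is infinite", stacklevel=2)
        return np.inf
    dists = np.linalg.norm(true_pos[:, None, :] - est_pos[None, :, :], axis=2)
    return float(dists.min(axis=1).mean() * 1000.0)


def active_volume(aset: ActiveSet, source_space: SourceSpace) -> float:
    """Active volume in cm^3: member count times the lattice voxel volume."""
    if aset.indices and max(aset.indices) >= source_space.count:
        raise InputContractError("active index outside the source space")
    return len(aset.indices) * source_space.voxel_volume


def nrmse(true_trace: np.ndarray, est_trace: np.ndarray) -> float:
    """RMS difference between energy-normalized envelopes of two traces."""
    t = np.asarray(true_trace, dtype=float)
    e = np.asarray(est_trace, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise InputContractError("traces must be 1-D and of equal length")
    out = []
    for x in (t, e):
        energy = float(x @ x)
        if energy == 0.0:
            raise UndefinedMetricError("zero-energy trace has no normalized envelope")
        out.append(np.abs(hilbert(x / np.sqrt(energy))))
    return float(np.sqrt(np.mean((out[0] - out[1]) ** 2)))


def iou(true_set: ActiveSet, est_set: ActiveSet) -> float:
    """Intersection-over-union of active voxel sets, in percent."""
    union = true_set.indices | est_set.indices
    if not union:
        return 0.0
    inter = true_set.indices & est_set.indices
    return 100.0 * len(inter) / len(union)


def deep_point(source_space: SourceSpace, sensors: SensorArray) -> int:
    """Index of the dipole with the greatest mean distance from the sensors."""
    d = np.linalg.norm(
        source_space.positions[:, None, :] - sensors.positions[None, :, :], axis=2
    )
    return int(np.argmax(d.mean(axis=1)))


def depth_split(
    case_source_indices: np.ndarray,
    source_space: SourceSpace,
    sensors: SensorArray,
    fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Split single-focal test cases into deep and cortical subsets.

    ``case_source_indices`` holds each case's single active dipole index.
    Cases are ranked by their dipole's distance from the deep point; the
    closest ``fraction`` form the deep subset, the rest the cortical subset.
    Returns (deep_case_ids, cortical_case_ids) as positions into the input.
    """
    idx = np.asarray(case_source_indices, dtype=int)
    if idx.ndim != 1 or idx.size == 0:
        raise InputContractError("need a 1-D, non-empty list of focal case indices")
    dp = source_space.positions[deep_point(source_space, sensors)]
    dist = np.linalg.norm(source_space.positions[idx] - dp, axis=1)
    order = np.argsort(dist, kind="stable")
    n_deep = int(round(fraction * idx.size))
    return order[:n_deep], order[n_deep:]
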