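"""Classical inverse solvers: LCMV, residual-variance scan, MNE, eLORETA.

All solvers operate on the same fixed-orientation scalar leadfield and sensor
recording containers as the neural reconstruction path, so benchmark
comparisons share one data model.

Conventions
-----------
* LCMV: unit-gain minimum-variance spatial filter per dipole,
  ``w_i = C^-1 l_i / (l_i^T C^-1 l_i)``.
* RV scan: single-dipole least squares at every grid point, scored by the
  residual fraction of data power (0 = perfect fit).
* MNE: Tikhonov-regularized minimum-L2-norm solution
  ``Q = L^T (L L^T + lambda I)^-1 M``.
* eLORETA: weighted minimum norm with depth weights iterated to the
  fixed point ``w_i = sqrt(l_i^T (L W^-1 L^T + alpha H)^+ l_i)``, which gives
  exact localization of single point sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientDataError,
    InputContractError,
    NumericalConditioningError,
)
from .forward import Leadfield
from .signals import SensorRecording

__all__ = [
    "Covariance",
    "InverseSolution",
    "estimate_covariance",
    "solve_lcmv",
    "solve_mne",
    "solve_eloreta",
    "solve_rv_scan",
    "default_regularization",
]

#: relative eigenvalue cutoff for pseudo-inverses
PINV_RTOL = 1e-12


@dataclass(frozen=True)
class Covariance:
    """S x S sensor covariance [tesla^2] with its diagonal-loading record."""

    matrix: np.ndarray
    loading_fraction: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InputContractError("covariance must be square")
        if not np.allclose(m, m.T, atol=1e-12 * max(1.0, np.abs(m).max())):
            raise InputContractError("covariance must be symmetric")


@dataclass(frozen=True)
class InverseSolution:
    """Estimated D x T source amplitudes (or D scan scores for RV)."""

    amplitudes: np.ndarray
    method: str
    hyperparameters: dict = field(default_factory=dict)
    scores: np.ndarray | None = None  # RV scan: residual-variance per dipole
    converged: bool = True
    n_iter: int = 0


def estimate_covariance(
    recording: SensorRecording, loading_fraction: float = 0.05
) -> Covariance:
    """Sample covariance over time (mean removed) with diagonal loading.

    Loading adds ``loading_fraction * trace(C)/S`` to the diagonal, the usual
    cure for rank-deficient sample estimates.
    """
    m = recording.samples
    if m.shape[1] < 2:
        raise InsufficientDataError("need at least 2 time samples for covariance")
    centered = m - m.mean(axis=1, keepdims=True)
    c = centered @ centered.T / (m.shape[1] - 1)
    s = c.shape[0]
    loaded = c + loading_fraction * (np.trace(c) / s) * np.eye(s)
    return Covariance(matrix=loaded, loading_fraction=loading_fraction)


def default_regularization(leadfield: Leadfield) -> float:
    """Conventional scale-aware regularizer: 0.05 * trace(L L^T) / S."""
    gain = leadfield.gain
    return 0.05 * float(np.einsum("ij,ij->", gain, gain)) / gain.shape[0]


def solve_lcmv(
    leadfield: Leadfield,
    covariance: Covariance,
    recording: SensorRecording,
) -> InverseSolution:
    """Linearly constrained minimum-variance beamformer, scalar per dipole.

    Each dipole's spatial filter minimizes output variance subject to unit
    gain at that dipole; singular covariances are rejected with a pointer to
    diagonal loading.
    """
    gain = leadfield.gain
    c = covariance.matrix
    try:
        cinv_l = np.linalg.solve(c, gain)  # (S, D)
    except np.linalg.LinAlgError as exc:
        raise NumericalConditioningError(
            "covariance is singular; re-estimate with diagonal loading "
            "(loading_fraction > 0)"
        ) from exc
    cond = np.linalg.cond(c)
    if not np.isfinite(cond) or cond > 1e14:
        raise NumericalConditioningError(
            f"covariance condition number {cond:.2e}; increase diagonal loading"
        )
    denom = np.einsum("sd,sd->d", gain, cinv_l)  # l_i^T C^-1 l_i
    silent = denom == 0  # zero leadfield columns have no unit-gain filter
    filters = cinv_l / np.where(silent, 1.0, denom)
    filters[:, silent] = 0.0
    amplitudes = filters.T @ recording.samples
    return InverseSolution(
        amplitudes=amplitudes,
        method="lcmv",
        hyperparameters={
            "loading_fraction": covariance.loading_fraction,
            "silent_columns": int(silent.sum()),
        },
    )


def solve_mne(
    leadfield: Leadfield, recording: SensorRecording, lam: float | None = None
) -> InverseSolution:
    """Minimum-norm estimate with Tikhonov regularization ``lam``.

    With ``lam=None`` the regularizer is set from the recording's known SNR
    (discrepancy-style, ``trace(LL^T)/(S * snr_linear)``) when available, else
    the conventional ``0.05 trace(LL^T)/S``.
    """
    gain = leadfield.gain
    s = gain.shape[0]
    if lam is None:
        if np.isfinite(recording.snr_db):
            snr_linear = 10.0 ** (recording.snr_db / 10.0)
            lam = float(np.einsum("ij,ij->", gain, gain)) / (s * snr_linear)
        else:
            lam = default_regularization(leadfield)
    if lam < 0:
        raise InputContractError(f"lambda must be >= 0, got {lam}")
    gram = gain @ gain.T + lam * np.eye(s)
    if lam == 0 and np.linalg.matrix_rank(gram) < s:
        raise NumericalConditioningError(
            "L L^T is rank-deficient and lambda is 0; use lambda > 0"
        )
    amplitudes = gain.T @ np.linalg.solve(gram, recording.samples)
    return InverseSolution(
        amplitudes=amplitudes, method="mne", hyperparameters={"lambda": lam}
    )


def _pinv_psd(a: np.ndarray) -> np.ndarray:
    """Pseudo-inverse of a symmetric PSD matrix by eigen-truncation."""
    vals, vecs = np.linalg.eigh(a)
    cutoff = PINV_RTOL * vals.max(initial=0.0)
    inv_vals = np.where(vals > cutoff, 1.0 / np.where(vals > cutoff, vals, 1.0), 0.0)
    return (vecs * inv_vals) @ vecs.T


def solve_eloreta(
    leadfield: Leadfield,
    recording: SensorRecording,
    alpha: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> InverseSolution:
    """eLORETA: depth-weighted minimum norm with iterated weights.

    Iterates ``w_i <- sqrt(l_i^T (L W^-1 L^T + alpha H)^+ l_i)`` (H = identity
    for magnetometer data) from ``w_i = 1`` until the largest relative weight
    change drops below ``tol``; on non-convergence the best iterate is
    returned with ``converged=False``.
    """
    gain = leadfield.gain
    if alpha is None:
        alpha = default_regularization(leadfield)
    if not alpha > 0:
        raise InputContractError(f"alpha must be > 0, got {alpha}")
    s = gain.shape[0]
    h = np.eye(s)
    # silent (all-zero) columns get unit weight; they contribute nothing to K
    # and receive zero amplitude regardless
    silent = np.einsum("sd,sd->d", gain, gain) == 0
    w = np.ones(gain.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        k = (gain / w) @ gain.T + alpha * h  # L W^-1 L^T + alpha H
        kinv = _pinv_psd(k)
        new_w = np.sqrt(np.einsum("sd,st,td->d", gain, kinv, gain))
        new_w[silent] = 1.0
        rel_change = np.max(np.abs(new_w - w) / np.maximum(np.abs(w), 1e-300))
        w = new_w
        if rel_change < tol:
            converged = True
            break
    k = (gain / w) @ gain.T + alpha * h
    amplitudes = (gain / w).T @ (_pinv_psd(k) @ recording.samples)
    return InverseSolution(
        amplitudes=amplitudes,
        method="eloreta",
        hyperparameters={"alpha": alpha, "tol": tol, "max_iter": max_iter},
        converged=converged,
        n_iter=n_iter,
    )


def solve_rv_scan(leadfield: Leadfield, recording: SensorRecording) -> InverseSolution:
    """Residual-variance single-dipole scan.

    Fits one dipole at each grid point by least squares and scores it by the
    unexplained fraction of sensor-data power; lower is better.  Silent
    (all-zero) leadfield columns receive score 1.
    """
    gain = leadfield.gain
    m = recording.samples
    data_power = float(np.einsum("st,st->", m, m))
    if data_power == 0:
        raise InputContractError("recording is identically zero")
    col_norms_sq = np.einsum("sd,sd->d", gain, gain)
    silent = col_norms_sq == 0
    safe_norms = np.where(silent, 1.0, col_norms_sq)
    amplitudes = (gain.T @ m) / safe_norms[:, None]  # (D, T) least-squares fits
    amplitudes[silent] = 0.0
    # residual via Pythagoras: ||M - l q||^2 = ||M||^2 - ||l q||^2 for LS fit
    explained = np.einsum("dt,dt->d", gain.T @ m, amplitudes)
    scores = 1.0 - explained / data_power
    scores = np.clip(scores, 0.0, 1.0)
    scores[silent] = 1.0
    return InverseSolution(
        amplitudes=amplitudes,
        method="rv",
        hyperparameters={"silent_columns": int(silent.sum())},
        scores=scores,
    )
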