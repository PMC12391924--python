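"""Synthetic head/helmet geometry for a spherically symmetric conductor model.

The measurement device is an array of radial magnetometers (SQUID-style) laid
out quasi-uniformly on a spherical cap above the head; the source space is a
regular cubic lattice of current dipoles inside a sphere concentric with the
sensor shell.  All coordinates are in meters, head-centered.

Dipoles are given fixed *tangential* unit orientations (orthogonal to their
position vector): in a spherically symmetric conductor the radial component of
a dipole moment produces no external magnetic field, so only the tangential
part is observable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidGeometryError

__all__ = [
    "SensorArray",
    "SourceSpace",
    "build_sensor_helmet",
    "build_source_grid",
    "read_geometry_tsv",
    "write_geometry_tsv",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: fallback orientation for a dipole at the exact origin, where "tangential"
#: is undefined
ORIGIN_ORIENTATION = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class SensorArray:
    """Radial magnetometer array on a sphere.

    Parameters
    ----------
    positions : (S, 3) float array
        Sensor positions in meters, head-centered.
    orientations : (S, 3) float array
        Unit sensing directions; radial, i.e. parallel to the position vector.
    """

    positions: np.ndarray
    orientations: np.ndarray

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape != ori.shape:
            raise InvalidGeometryError(
                f"positions/orientations must be matching (S, 3) arrays, "
                f"got {pos.shape} and {ori.shape}"
            )
        radii = np.linalg.norm(pos, axis=1)
        if np.any(radii == 0):
            raise InvalidGeometryError("sensor at the head center")
        norms = np.linalg.norm(ori, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise InvalidGeometryError("sensor orientations must be unit vectors")
        # radial sensing assumption: orientation parallel to position
        cosines = np.abs(np.einsum("ij,ij->i", pos, ori) / radii)
        if np.any(np.abs(cosines - 1.0) > 1e-10):
            raise InvalidGeometryError("sensor orientations must be radial")

    @property
    def count(self) -> int:
        return self.positions.shape[0]

    @property
    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.positions).tobytes())
        h.update(np.ascontiguousarray(self.orientations).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class SourceSpace:
    """Regular cubic lattice of fixed-orientation current dipoles.

    ``voxel_volume`` is the lattice cell volume in cm^3 (``spacing`` is in
    meters); it converts active-dipole counts into activated brain volume.
    """

    positions: np.ndarray
    orientations: np.ndarray
    spacing: float
    radius: float = field(default=np.nan)

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape != ori.shape:
            raise InvalidGeometryError(
                f"positions/orientations must be matching (D, 3) arrays, "
                f"got {pos.shape} and {ori.shape}"
            )
        if not self.spacing > 0:
            raise InvalidGeometryError("lattice spacing must be positive")
        norms = np.linalg.norm(ori, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-10):
            raise InvalidGeometryError("dipole orientations must be unit vectors")
        radii = np.linalg.norm(pos, axis=1)
        off_origin = radii > 0
        dots = np.abs(np.einsum("ij,ij->i", pos[off_origin], ori[off_origin]))
        if dots.size and np.any(dots / radii[off_origin] > 1e-10):
            raise InvalidGeometryError("dipole orientations must be tangential")

    @property
    def count(self) -> int:
        return self.positions.shape[0]

    @property
    def voxel_volume(self) -> float:
        """Lattice cell volume in cm^3."""
        return (self.spacing * 100.0) ** 3

    @property
    def max_radius(self) -> float:
        return float(np.linalg.norm(self.positions, axis=1).max())

    def lattice_indices(self) -> np.ndarray:
        """Integer lattice coordinates of every dipole (D, 3)."""
        return np.rint(self.positions / self.spacing).astype(int)

    def neighbor_pairs(self) -> np.ndarray:
        """Index pairs of 6-neighborhood (face-adjacent) lattice neighbors."""
        idx = self.lattice_indices()
        lookup = {tuple(v): i for i, v in enumerate(idx)}
        pairs = []
        for i, v in enumerate(idx):
            for axis in range(3):
                for step in (-1, 1):
                    w = list(v)
                    w[axis] += step
                    j = lookup.get(tuple(w))
                    if j is not None and j > i:
                        pairs.append((i, j))
        return np.array(pairs, dtype=int).reshape(-1, 2)

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.positions).tobytes())
        h.update(np.ascontiguousarray(self.orientations).tobytes())
        h.update(np.float64(self.spacing).tobytes())
        return h.hexdigest()


def build_sensor_helmet(
    n_sensors: int, radius: float = 0.12, cap_fraction: float = 0.6
) -> SensorArray:
    """Lay out radial magnetometers on the upper spherical cap.

    Uses a Fibonacci spiral restricted to the cap covering ``cap_fraction`` of
    the sphere's surface (a helmet-like coverage), which gives a quasi-uniform
    packing for any sensor count.

    Parameters
    ----------
    n_sensors : int
        Number of magnetometers.
    radius : float
        Sensor shell radius in meters.  Must strictly exceed the source-space
        radius it will be paired with.
    cap_fraction : float
        Fraction of the full sphere surface covered by the helmet, in (0, 1].
    """
    if n_sensors <= 0:
        raise InvalidGeometryError(f"n_sensors must be positive, got {n_sensors}")
    if not radius > 0:
        raise InvalidGeometryError(f"radius must be positive, got {radius}")
    if not 0 < cap_fraction <= 1:
        raise InvalidGeometryError(
            f"cap_fraction must be in (0, 1], got {cap_fraction}"
        )
    if n_sensors == 1:
        pos = np.array([[0.0, 0.0, radius]])
    else:
        i = np.arange(n_sensors)
        # cap area fraction f corresponds to z/r in [1 - 2f, 1]
        z = 1.0 - 2.0 * cap_fraction * (i + 0.5) / n_sensors
        rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        phi = i * _GOLDEN_ANGLE
        pos = radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    ori = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return SensorArray(positions=pos, orientations=ori)


def _tangential_orientations(positions: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic pseudo-random unit tangents, one per dipole."""
    rng = np.random.default_rng(seed)
    ori = np.empty_like(positions)
    for i, p in enumerate(positions):
        r = np.linalg.norm(p)
        if r == 0:
            ori[i] = ORIGIN_ORIENTATION
            continue
        rhat = p / r
        while True:
            v = rng.standard_normal(3)
            t = v - (v @ rhat) * rhat
            n = np.linalg.norm(t)
            if n > 1e-6:
                ori[i] = t / n
                break
    return ori


def build_source_grid(
    radius: float = 0.08, spacing: float = 0.005, orientation_seed: int = 0
) -> SourceSpace:
    """Build a cubic dipole lattice inside a sphere.

    The lattice is centered at the origin; points with norm strictly below
    ``radius`` are retained.  Each dipole receives a fixed unit tangential
    orientation drawn deterministically from ``orientation_seed``.  A dipole at
    the exact origin (present whenever the lattice is origin-centered) has no
    tangential direction and is assigned :data:`ORIGIN_ORIENTATION`.
    """
    if not spacing > 0:
        raise InvalidGeometryError(f"spacing must be positive, got {spacing}")
    if not radius > 0:
        raise InvalidGeometryError(f"radius must be positive, got {radius}")
    # a spacing coarser than the sphere still yields the origin-only lattice
    m = int(np.ceil(radius / spacing))
    axis = np.arange(-m, m + 1)
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    pos = grid * spacing
    keep = np.linalg.norm(pos, axis=1) < radius
    pos = pos[keep]
    # deterministic ordering: sort by (z, y, x)
    order = np.lexsort((pos[:, 0], pos[:, 1], pos[:, 2]))
    pos = pos[order]
    ori = _tangential_orientations(pos, orientation_seed)
    return SourceSpace(positions=pos, orientations=ori, spacing=spacing, radius=radius)


def write_geometry_tsv(path: str | Path, obj: SensorArray | SourceSpace) -> None:
    """Write sensor or source geometry as TSV (x, y, z, ox, oy, oz in meters).

    Rows are 0-based in the same order as the in-memory arrays.
    """
    df = pd.DataFrame(
        np.hstack([obj.positions, obj.orientations]),
        columns=["x", "y", "z", "ox", "oy", "oz"],
    )
    with open(path, "w") as fh:
        fh.write("# positions x,y,z in meters; orientations ox,oy,oz unit vectors\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_geometry_tsv(
    path: str | Path, kind: str = "sensors", spacing: float | None = None
) -> SensorArray | SourceSpace:
    """Read geometry written by :func:`write_geometry_tsv`.

    ``kind`` selects the container: ``"sensors"`` or ``"sources"`` (the latter
    requires ``spacing`` to reconstruct voxel volumes).
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    pos = df[["x", "y", "z"]].to_numpy(float)
    if {"ox", "oy", "oz"}.issubset(df.columns):
        ori = df[["ox", "oy", "oz"]].to_numpy(float)
    else:
        ori = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    if kind == "sensors":
        return SensorArray(positions=pos, orientations=ori)
    if kind == "sources":
        if spacing is None:
            raise InvalidGeometryError("spacing required to read a source grid")
        return SourceSpace(positions=pos, orientations=ori, spacing=spacing)
    raise InvalidGeometryError(f"unknown geometry kind {kind!r}")
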