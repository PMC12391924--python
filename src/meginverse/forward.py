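"""Forward model: radial magnetometer leadfield in a spherical conductor.

For a spherically symmetric conductor the volume currents contribute nothing
to the *radial* component of the external magnetic field, which therefore has
the closed form

    B_r(r) = (mu0 / 4 pi) * [(r x r_q) . q] / (|r| * |r - r_q|^3)

for a current dipole with moment ``q`` at position ``r_q`` and a sensor at
``r`` measuring along ``r/|r|``.  Stacking this scalar over sensors and grid
dipoles (with fixed unit orientations folded in) yields the S x D leadfield
matrix ``L`` of the linear measurement model ``M = L Q + N``.

Units: SI.  Positions in meters, dipole moments in A*m, field in tesla; the
gain matrix is tesla per (A*m).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidGeometryError, SingularGeometryError
from .geometry import SensorArray, SourceSpace

__all__ = [
    "MU0",
    "Leadfield",
    "leadfield_entry",
    "assemble_leadfield",
    "save_leadfield",
    "load_leadfield",
]

#: free-space magnetic permeability [H/m]
MU0 = 4e-7 * np.pi


@dataclass(frozen=True)
class Leadfield:
    """S x D gain matrix plus identity of the geometries it was built from."""

    gain: np.ndarray
    sensors: SensorArray
    sources: SourceSpace

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        object.__setattr__(self, "gain", g)
        if g.shape != (self.sensors.count, self.sources.count):
            raise InvalidGeometryError(
                f"gain shape {g.shape} does not match S={self.sensors.count}, "
                f"D={self.sources.count}"
            )
        if not np.all(np.isfinite(g)):
            raise InvalidGeometryError("leadfield contains non-finite entries")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


def leadfield_entry(
    sensor_position: np.ndarray,
    dipole_position: np.ndarray,
    dipole_orientation: np.ndarray,
) -> float:
    """Radial field at one sensor from a unit dipole [T / (A*m)].

    Linear in ``dipole_orientation``; zero for radial orientations (silent
    sources) and for a dipole at the head center.
    """
    r = np.asarray(sensor_position, dtype=float)
    rq = np.asarray(dipole_position, dtype=float)
    theta = np.asarray(dipole_orientation, dtype=float)
    rn = np.linalg.norm(r)
    if rn == 0:
        raise SingularGeometryError("sensor at the head center")
    d = np.linalg.norm(r - rq)
    if d == 0:
        raise SingularGeometryError("sensor and dipole positions coincide")
    return float(MU0 / (4 * np.pi) * np.cross(r, rq) @ theta / (rn * d**3))


def assemble_leadfield(sensors: SensorArray, sources: SourceSpace) -> Leadfield:
    """Assemble the S x D leadfield for fixed-orientation grid dipoles.

    Vectorized evaluation of :func:`leadfield_entry` over all sensor/dipole
    pairs; requires every source strictly inside the sensor shell.
    """
    rs = sensors.positions  # (S, 3)
    rq = sources.positions  # (D, 3)
    theta = sources.orientations  # (D, 3)
    sensor_radii = np.linalg.norm(rs, axis=1)
    source_radii = np.linalg.norm(rq, axis=1)
    if source_radii.max(initial=0.0) >= sensor_radii.min():
        raise InvalidGeometryError(
            "every source must lie strictly inside the sensor shell "
            f"(max source radius {source_radii.max():.4g} m, "
            f"min sensor radius {sensor_radii.min():.4g} m)"
        )
    cross = np.cross(rs[:, None, :], rq[None, :, :])  # (S, D, 3)
    numer = np.einsum("sdk,dk->sd", cross, theta)
    diff = rs[:, None, :] - rq[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    gain = MU0 / (4 * np.pi) * numer / (sensor_radii[:, None] * dist**3)
    return Leadfield(gain=gain, sensors=sensors, sources=sources)


def save_leadfield(path: str | Path, lf: Leadfield) -> None:
    """Persist a leadfield with geometry checksums (HDF5 bundle)."""
    from .bundle import ArrayBundle, save_bundle

    bundle = ArrayBundle(
        arrays={
            "gain": lf.gain,
            "sensor_positions": lf.sensors.positions,
            "sensor_orientations": lf.sensors.orientations,
            "source_positions": lf.sources.positions,
            "source_orientations": lf.sources.orientations,
        },
        meta={
            "kind": "leadfield",
            "sensor_checksum": lf.sensors.checksum(),
            "source_checksum": lf.sources.checksum(),
            "spacing": lf.sources.spacing,
            "radius": float(lf.sources.radius),
        },
    )
    save_bundle(path, bundle)


def load_leadfield(path: str | Path) -> Leadfield:
    """Load a leadfield bundle, re-validating geometry checksums."""
    from .bundle import load_bundle

    b = load_bundle(path)
    sensors = SensorArray(
        positions=b.arrays["sensor_positions"],
        orientations=b.arrays["sensor_orientations"],
    )
    sources = SourceSpace(
        positions=b.arrays["source_positions"],
        orientations=b.arrays["source_orientations"],
        spacing=float(b.meta["spacing"]),
        radius=float(b.meta["radius"]),
    )
    from .errors import CorruptBundleError

    if sensors.checksum() != b.meta["sensor_checksum"]:
        raise CorruptBundleError("sensor geometry checksum mismatch")
    if sources.checksum() != b.meta["source_checksum"]:
        raise CorruptBundleError("source geometry checksum mismatch")
    return Leadfield(gain=b.arrays["gain"], sensors=sensors, sources=sources)
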