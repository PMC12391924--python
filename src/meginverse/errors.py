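"""Exception hierarchy.

All package-specific failures derive from :class:`MegInverseError` so callers
can catch one base class at the CLI boundary.
"""


class MegInverseError(Exception):
    """Base class for all meginverse errors."""


class InvalidGeometryError(MegInverseError):
    """Sensor/source geometry violates a physical or layout constraint."""


class SingularGeometryError(MegInverseError):
    """Degenerate geometry (e.g. coincident sensor and dipole positions)."""


class InvalidConfigError(MegInverseError):
    """A configuration value or combination is invalid."""


class InvalidParameterError(MegInverseError):
    """A signal/model parameter is outside its admissible domain."""


class ScenarioGenerationError(MegInverseError):
    """An activation scenario could not be generated under the constraints."""


class UndefinedSNRError(MegInverseError):
    """SNR is undefined (zero clean signal with finite requested SNR)."""


class InsufficientDataError(MegInverseError):
    """Not enough samples for the requested estimate."""


class NumericalConditioningError(MegInverseError):
    """A linear system is too ill-conditioned to solve reliably."""


class InputContractError(MegInverseError):
    """An array argument violates a shape/compatibility contract."""


class UndefinedMetricError(MegInverseError):
    """A metric is undefined for the given inputs (e.g. zero-energy trace)."""


class CorruptBundleError(MegInverseError):
    """An array bundle on disk fails its manifest validation."""
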