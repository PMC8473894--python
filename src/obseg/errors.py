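"""Exception hierarchy used across the pipeline."""

import math


class ObsegError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(ObsegError, ValueError):
    """Affine/grid mismatch or degenerate voxel-to-world map."""


class ShapeError(ObsegError, ValueError):
    """Array rank or dimension violates an operation's contract."""


class ParameterError(ObsegError, ValueError):
    """Invalid user-supplied parameter value."""


class SpecError(ObsegError, ValueError):
    """A network/phantom specification violates its invariants."""


class EmptyStructureError(ObsegError, ValueError):
    """An operation that needs foreground voxels received none."""


class LocalizationError(ObsegError, RuntimeError):
    """Stage-1 localization failed; carries a fallback centroid for QC."""

    def __init__(self, message, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class UndefinedDistanceError(ObsegError, ValueError):
    """Distance metric undefined (empty mask); carries an infinity sentinel."""

    def __init__(self, message, value=math.inf):
        super().__init__(message)
        self.value = value


class ConfigurationError(ObsegError, ValueError):
    """Checkpoint/ensemble configuration inconsistent with the pipeline."""


class DataError(ObsegError, ValueError):
    """Malformed tabular/measurement input."""
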