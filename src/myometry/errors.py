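"""Classified error types.

Every validation failure in the toolkit raises one of these, so callers
(and the CLI exit-code mapping) can distinguish bad inputs (ValidationError
family) from computation failures (ComputationError family).
"""


class MyometryError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(MyometryError):
    """Invalid input data or parameters."""


class DimensionalityError(ValidationError):
    """Volume is not 3D."""


class HeaderError(ValidationError):
    """Bad header metadata (e.g. non-positive voxel spacing)."""


class IntensityError(ValidationError):
    """Negative or non-finite intensities in a signal volume."""


class AlignmentError(ValidationError):
    """Two grids that must match (shape/spacing/percent grid) do not."""


class DictionaryError(ValidationError):
    """Label codes present in a grid but missing from the dictionary."""


class EmptyMuscleError(ValidationError):
    """A requested label code has no voxels."""


class ParameterError(ValidationError):
    """Out-of-range analysis parameter."""


class SpecError(ValidationError):
    """Invalid phantom specification (e.g. overlapping muscle geometry)."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested statistic."""


class DomainError(ValidationError):
    """Value outside the statistic's domain (e.g. non-positive volume)."""


class ComputationError(MyometryError):
    """A numerical stage failed."""


class RegistrationError(ComputationError):
    """Registration did not converge; carries the best transform found."""

    def __init__(self, message, best_transform=None, metric_trace=None):
        super().__init__(message)
        self.best_transform = best_transform
        self.metric_trace = metric_trace or []


class UndefinedOverlapError(ComputationError):
    """Overlap requested for a code empty in both maps."""


class ConfigurationError(ValidationError):
    """Inconsistent run configuration."""
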