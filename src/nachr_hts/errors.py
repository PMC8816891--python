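"""Exception hierarchy for screening-data errors.

All package errors derive from :class:`NachrHtsError` so callers can catch
one base class at pipeline boundaries.
"""


class NachrHtsError(Exception):
    """Base class for all package errors."""


class FormatError(NachrHtsError):
    """A file does not have the expected columns or shape."""


class DataError(NachrHtsError):
    """Well-level data violates an invariant (duplicates, negatives, missing reads)."""


class CapacityError(NachrHtsError):
    """Requested control/titration wells exceed the plate's interior capacity."""


class ConfigurationError(NachrHtsError):
    """A run configuration is incomplete or inconsistent (e.g. missing compound truth)."""


class DomainError(NachrHtsError):
    """A numeric argument is outside its valid domain (e.g. non-positive concentration)."""


class InsufficientDataError(NachrHtsError):
    """Too few observations to compute the requested statistic."""


class UndefinedMetricError(NachrHtsError):
    """The statistic is undefined for these inputs (zero mean, equal means, zero variance)."""


class DegeneratePlateError(NachrHtsError):
    """Plate controls do not separate; normalization is impossible."""


class InvalidPlateError(NachrHtsError):
    """An efflux plate has non-positive specific efflux and cannot be analyzed."""
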