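"""Exception hierarchy.

Errors are grouped so the CLI can map them onto exit codes:
``ConfigError`` -> 2 (validation), everything else -> 3 (data).
"""


class PostureKitError(Exception):
    """Base class for all posturekit errors."""


class ConfigError(PostureKitError):
    """Invalid configuration, registry mismatch, or contract violation."""


class FormatError(PostureKitError):
    """A file does not match its declared dialect/format."""


class EmptyInputError(PostureKitError):
    """An input file or sequence contains no usable data."""


class InsufficientDataError(PostureKitError):
    """Too few samples/rows/participants for the requested operation."""


class NoImpulseError(PostureKitError):
    """No synchronization impulse of sufficient prominence was found."""


class AlignmentError(PostureKitError):
    """A session cannot be aligned (e.g. a placement lacks a sync event)."""


class UndefinedMetricError(PostureKitError):
    """A statistic is undefined for the given inputs (zero variance, no overlap...)."""


class DegenerateModelError(PostureKitError):
    """Training data cannot support a classifier (e.g. a single class)."""
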