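"""Typed exceptions used across the package.

Every user-facing failure mode raises one of these; the CLI maps them to
exit codes (2 = configuration, 3 = data, 4 = fitting).
"""


class RunoffKitError(Exception):
    """Base class for all runoffkit errors."""


class FormatError(RunoffKitError):
    """A file could not be parsed (bad cell, too few rows, wrong columns)."""


class GeometryError(RunoffKitError):
    """Trace geometry is invalid, e.g. non-monotone gradient positions."""


class ParameterError(RunoffKitError):
    """A parameter is out of its valid range."""


class IdempotenceError(RunoffKitError):
    """An operation was applied twice that must be applied once."""


class PeakNotFoundError(RunoffKitError):
    """A required peak was absent from its search window."""


class SegmentationError(RunoffKitError):
    """Region segmentation is inconsistent with the trace span."""


class DivisionError(RunoffKitError):
    """A ratio with a zero reference was requested."""


class FitError(RunoffKitError):
    """A model fit is impossible (too few points, zero residual df)."""


class DesignError(RunoffKitError):
    """The experimental design table is incomplete or inconsistent."""


class NormalizationError(RunoffKitError):
    """Normalization cannot proceed (e.g. a near-empty sample)."""
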