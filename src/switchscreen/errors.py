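"""Exception types shared across the pipeline.

Every stage raises one of these rather than a bare ValueError so that the
pipeline driver can report which stage and which sample failed.
"""


class SwitchScreenError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SwitchScreenError):
    """A caller-supplied parameter is outside its documented domain."""


class SchemaError(SwitchScreenError):
    """A table is missing required columns or has malformed rows."""


class ConfigError(SwitchScreenError):
    """A configuration object is incomplete or inconsistent."""


class InsufficientDataError(SwitchScreenError):
    """An operation requires data (events, cells) that is not there."""


class DivisionDomainError(SwitchScreenError):
    """A normalization denominator is zero or non-positive."""


class DegenerateProfileError(SwitchScreenError):
    """A centered fold-change profile has zero norm (no effect on any switch)."""


class DegenerateMeasurementError(SwitchScreenError):
    """An observed gate-output vector is identically zero."""
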