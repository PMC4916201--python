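"""Exception hierarchy shared across the package.

Every failure mode the library raises deliberately derives from
:class:`NeuroIndexError` so callers can catch package errors as one family
while the specific subclasses keep test assertions precise.
"""


class NeuroIndexError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(NeuroIndexError):
    """A delimited text cell could not be parsed as a number."""


class LayoutError(NeuroIndexError):
    """Channel count does not match the supplied or default channel map."""


class DataError(NeuroIndexError):
    """Input data violates a content requirement (NaN/Inf, all-zero, ...)."""


class ChannelNotFoundError(NeuroIndexError):
    """A requested channel label is absent from a recording or PSD."""


class GridError(NeuroIndexError):
    """Two spectra that must share a frequency grid do not."""


class DurationError(NeuroIndexError):
    """A recording or signal is too short for the requested operation."""


class ParameterError(NeuroIndexError):
    """An operation parameter is outside its documented domain."""


class DomainError(NeuroIndexError):
    """A scalar argument is outside the mathematical domain of a formula."""


class ConfigError(NeuroIndexError):
    """A generator or pipeline configuration is invalid."""


class DetectionError(NeuroIndexError):
    """QRS detection found no usable peaks."""
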