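"""Exception hierarchy shared by all icount modules."""


class ICountError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ICountError):
    """Unreadable file or unsupported image format."""


class BoundsError(ICountError):
    """A rectangle or index falls outside the image it refers to."""


class ParameterError(ICountError):
    """A detection or generator parameter is outside its valid range."""


class ConsistencyError(ICountError):
    """Two inputs that must describe the same image or objects disagree."""


class ValidationError(ICountError):
    """A user-supplied value (e.g. a review correction) is invalid."""


class StatisticsError(ICountError):
    """A statistical routine received degenerate input."""


class CapacityError(ICountError):
    """A synthetic strip cannot host the requested eggs at the requested gap."""
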