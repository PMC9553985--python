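"""Exception hierarchy shared across the package."""


class TcrscopeError(Exception):
    """Base class for all package errors."""


class FormatError(TcrscopeError):
    """A clonotype table does not conform to the requested dialect."""


class EmptyRepertoireError(TcrscopeError):
    """An operation produced or received a repertoire with no usable clonotypes."""


class ArgumentError(TcrscopeError, ValueError):
    """Invalid argument combination."""


class StateError(TcrscopeError, RuntimeError):
    """Object is not in the state required by the operation (e.g. uncalibrated model)."""


class InsufficientDataError(TcrscopeError):
    """Too little data for the requested statistic (overlap, pairs, matches...)."""


class MatchingError(TcrscopeError):
    """Age matching could not satisfy the caliper/ratio constraints."""


class CalibrationWarning(UserWarning):
    """Degenerate score distribution during threshold calibration."""
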