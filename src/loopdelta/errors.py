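"""Exception hierarchy shared across loopdelta modules."""


class LoopdeltaError(Exception):
    """Base class for all package errors."""


class ConfigError(LoopdeltaError, ValueError):
    """Invalid configuration value or combination."""


class FormatError(LoopdeltaError, ValueError):
    """Malformed input file; message carries the offending line when known."""


class ValidationError(LoopdeltaError, ValueError):
    """Semantically invalid record (e.g. start >= end)."""


class AlignmentError(LoopdeltaError, ValueError):
    """Two inputs that must share a bin table do not."""


class StateError(LoopdeltaError, RuntimeError):
    """Operation called on an object in the wrong state (e.g. unbalanced matrix)."""


class ConvergenceError(LoopdeltaError, RuntimeError):
    """Iterative procedure failed to converge; message carries the residual."""


class PlacementError(LoopdeltaError, RuntimeError):
    """Synthetic feature could not be placed without collision."""


class DegenerateMatrixError(LoopdeltaError, ValueError):
    """Numerically degenerate matrix (constant rows, zero variance)."""


class OrientationError(LoopdeltaError, ValueError):
    """Eigenvector sign cannot be fixed against the reference track."""
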