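"""Exception taxonomy shared across the package."""


class GranulenetError(Exception):
    """Base class for all package errors."""


class ParameterError(GranulenetError, ValueError):
    """Invalid user-supplied parameter (out of range, wrong shape spec...)."""


class ValidationError(GranulenetError, ValueError):
    """Invalid runtime data (length mismatch, non-finite features...)."""


class ShapeError(GranulenetError, ValueError):
    """Tensor shape incompatible with the layer/block contract."""


class StateError(GranulenetError, RuntimeError):
    """Operation requires a trained/built component that is missing."""


class TrainingError(GranulenetError, RuntimeError):
    """Training cannot proceed (e.g. a single-class dataset)."""


class UndefinedMetricError(GranulenetError, ZeroDivisionError):
    """Metric denominator is zero on a degenerate evaluation set."""
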