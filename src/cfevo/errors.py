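"""Exception types shared across the package."""


class CfEvoError(Exception):
    """Base class for all package errors."""


class InvalidArgument(CfEvoError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientData(CfEvoError, ValueError):
    """Not enough observations to compute the requested quantity."""


class GridMismatch(CfEvoError, ValueError):
    """Two profiles do not share the same bin grid."""


class UnsupportedSize(CfEvoError, ValueError):
    """Problem size exceeds the exhaustive-enumeration bound."""


class EstimationUnavailable(CfEvoError, ValueError):
    """A fallback estimator cannot be applied to this input."""
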