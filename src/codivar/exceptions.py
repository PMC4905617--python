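"""Exception and warning types shared across codivar."""


class CodivarError(Exception):
    """Base class for all codivar errors."""


class InvalidInputError(CodivarError, ValueError):
    """Malformed or non-conforming input data (shapes, labels, parsing)."""


class InvalidSpecError(CodivarError, ValueError):
    """A model specification that is infeasible for the given data."""


class DegenerateDataError(CodivarError, ValueError):
    """Data that is degenerate for the requested operation (e.g. all zero)."""


class NoCommonVariationError(CodivarError, ValueError):
    """Raised when the cross-block covariance is numerically zero, so no
    common variation can be estimated."""


class ConvergenceWarning(UserWarning):
    """An iterative routine stopped at its iteration cap before reaching
    its stationarity tolerance; the last iterate is returned."""
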