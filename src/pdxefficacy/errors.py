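"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data violate a structural or domain invariant."""


class NotEvaluableError(RuntimeError):
    """Raised when a quantity cannot be computed from the available data.

    Distinct from :class:`ValidationError`: the input is well-formed, but the
    study does not contain the measurements the requested quantity needs
    (e.g. no common measurement day between two arms).
    """


class BelowQuantificationError(ValueError):
    """Raised when a qPCR target is undetected and a point estimate is required."""
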