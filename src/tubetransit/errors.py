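"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A domain object was constructed with physically invalid parameters.

    The message always names the offending field.
    """


class ConfigError(ValidationError):
    """A run-configuration file failed to parse or validate."""


class RefinementError(RuntimeError):
    """The PDE oracle could not reach its refinement tolerance.

    Raised with guidance when the grid required by the cell Peclet
    number exceeds the solver's cell budget.
    """


class CalibrationError(RuntimeError):
    """Scalar calibration failed (bracket or monotonicity violation)."""
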