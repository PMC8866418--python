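"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An input parameter or parameter combination is physically or structurally invalid."""


class FormatError(ValueError):
    """An input table or file does not satisfy the expected format contract."""


class ContractError(ValueError):
    """Arguments violate an inter-argument contract (e.g. mismatched lengths or conditions)."""


class FitError(RuntimeError):
    """A correlation-decay fit failed (non-decaying curve, no usable lags, or no convergence)."""


class NumericalError(RuntimeError):
    """A quadrature or other numerical procedure failed to converge."""
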