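"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when a distribution, channel or system violates its invariants."""


class NumericalError(RuntimeError):
    """Raised when an iterative numerical routine fails (underflow, divergence)."""
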