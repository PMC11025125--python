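"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition or invariant."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative/numerical routine fails to meet its tolerance."""


class ExtrapolationError(ValueError):
    """Raised when an interpolation target lies outside the sampled range."""


class FitError(RuntimeError):
    """Raised when a least-squares fit cannot be performed or is rejected."""
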