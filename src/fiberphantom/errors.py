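"""Exception hierarchy shared across the package."""


class FiberPhantomError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FiberPhantomError, ValueError):
    """Raised when an input violates a documented precondition or invariant."""


class ExpressionError(ValidationError):
    """Raised when a parametric expression cannot be parsed or evaluated safely."""


class FormatError(FiberPhantomError, IOError):
    """Raised when a phantom file is malformed or has an unsupported version."""
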