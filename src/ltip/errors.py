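"""Exception hierarchy shared across the package."""


class LtipError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LtipError, ValueError):
    """A file or table does not match the declared format (e.g. a mapped
    column is absent from the header)."""


class ParseError(LtipError, ValueError):
    """A file exists but its contents cannot be parsed."""


class ValidationError(LtipError, ValueError):
    """Inputs violate a documented precondition (dimension mismatch,
    unknown identifier, out-of-range value, ...)."""


class NumericError(LtipError, ArithmeticError):
    """Non-finite values appeared where finite ones are required."""


class DegenerateVarianceError(LtipError, ValueError):
    """A correlation was requested on a constant vector."""
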