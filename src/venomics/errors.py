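"""Exception hierarchy shared across the package."""


class VenomicsError(Exception):
    """Base class for all package errors."""


class InvalidInputError(VenomicsError, ValueError):
    """Raised when input data violate a documented precondition."""


class ValidationError(InvalidInputError):
    """Raised when a parsed object fails structural validation."""


class NewickParseError(InvalidInputError):
    """Raised when a Newick string cannot be parsed."""


class NonBracketingError(InvalidInputError):
    """Raised when a dose-response series never brackets 50% mortality."""


class UndefinedSignalError(InvalidInputError):
    """Raised when Blomberg's K is undefined (constant trait)."""


class DegenerateContrastError(InvalidInputError):
    """Raised when an independent contrast has zero expected variance."""


class NumericError(VenomicsError):
    """Raised when a numerical routine fails beyond recovery (e.g. a
    covariance matrix stays singular after regularization)."""
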