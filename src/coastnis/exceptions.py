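"""Exception hierarchy shared across the package."""


class CoastnisError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CoastnisError):
    """A required column or structural element is missing from an input table."""


class ParseError(CoastnisError):
    """A cell could not be converted to the declared type; carries row/column context."""


class ValidationError(CoastnisError):
    """Values violate a domain invariant (range, uniqueness, coverage)."""


class CoverageError(ValidationError):
    """Coastline segments do not tile the requested window."""


class EmptySubsetError(CoastnisError):
    """A regional filter produced an empty dataset."""


class ConvergenceError(CoastnisError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []
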