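"""Exception hierarchy shared across the package."""


class EquiscaleError(Exception):
    """Base class for all package errors."""


class ValidationError(EquiscaleError, ValueError):
    """Raised when an input table or record violates a structural invariant.

    Carries optional ``row`` and ``field`` attributes naming the offending
    location so CLI error messages can point at the exact cell.
    """

    def __init__(self, message, *, row=None, field=None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if field is not None:
            loc.append(f"field '{field}'")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.field = field


class DomainError(EquiscaleError, ValueError):
    """An argument lies outside an operation's mathematical domain."""


class SingularFitError(EquiscaleError, ValueError):
    """A regression design matrix is rank-deficient (e.g. all x identical)."""


class UndefinedResultError(EquiscaleError, ZeroDivisionError):
    """A ratio is requested whose denominator is exactly zero."""


class ConfigError(EquiscaleError, ValueError):
    """A run or generator configuration is infeasible or malformed."""
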