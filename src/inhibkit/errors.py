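"""Exception hierarchy shared across the package."""


class InhibkitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(InhibkitError, ValueError):
    """A value violates a physical or structural precondition."""


class InsufficientDesignError(InhibkitError, ValueError):
    """The experimental design carries too few levels for the requested inference."""


class InconsistentDataError(InhibkitError, ValueError):
    """Derived quantities are physically impossible (e.g. negative rate constants)."""


class SchemaError(InhibkitError, ValueError):
    """A table is missing required columns or contains malformed rows."""
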