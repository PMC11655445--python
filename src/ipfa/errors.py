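"""Exception hierarchy for the ipfa package.

Exit-code mapping used by the CLI: validation/configuration/parse errors
exit with status 2, I/O problems with status 3.
"""


class IPFAError(Exception):
    """Base class for all errors raised by ipfa."""


class ParseError(IPFAError):
    """A malformed record or line in an input file; carries line context."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ConfigurationError(IPFAError):
    """An invalid parameter or option combination."""


class ValidationError(IPFAError):
    """Input data violates a contract (negative areas, duplicates, ...)."""


class SchemaError(ValidationError):
    """Tabular input does not match the expected column/metadata schema."""
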