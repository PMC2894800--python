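"""Exception taxonomy shared across the toolkit.

Validation problems (bad values, contract violations) and I/O problems
(unreadable or malformed files) are kept distinct so the command-line
layer can map them to conventional exit codes.
"""


class VarkitError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(VarkitError, ValueError):
    """A value violates a documented contract (bad parameter, bad record)."""


class CoordinateError(ValidationError):
    """A genomic coordinate or sequence name does not resolve."""


class ContractError(ValidationError):
    """An operation was invoked outside its stated precondition."""


class FormatError(VarkitError, IOError):
    """A file could not be parsed; carries the offending line when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)
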