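"""Exception types shared across the package."""


class CernetError(Exception):
    """Base class for all package errors."""


class ValidationError(CernetError, ValueError):
    """Invalid configuration or container contents.

    Carries ``fields``, the names of the offending fields, when applicable.
    """

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []


class ParseError(CernetError, ValueError):
    """Malformed input file; ``line`` is the 1-based offending line when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ConflictError(CernetError, ValueError):
    """An id was reused where uniqueness is required."""
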