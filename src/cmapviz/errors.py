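"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class ParserError(ValidationError):
    """A text input could not be parsed; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
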