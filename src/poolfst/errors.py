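"""Exception hierarchy shared across the pipeline."""


class PoolfstError(Exception):
    """Base class for all poolfst errors."""


class ConfigError(PoolfstError):
    """A run configuration is invalid (missing column, bad group layout...)."""


class ParseError(PoolfstError):
    """An input file row could not be parsed; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FormatError(PoolfstError):
    """An input file violates its format contract (coordinates, duplicate ids)."""


class ContractError(PoolfstError):
    """A precondition of a computational operation was violated."""
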