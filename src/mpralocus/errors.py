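"""Exception types shared across the package."""


class MpraError(Exception):
    """Base class for all package errors."""


class InputError(MpraError, ValueError):
    """Malformed or out-of-contract input."""


class CapacityError(MpraError, ValueError):
    """A combinatorial request exceeds the available design space."""


class ConfigError(MpraError, ValueError):
    """Invalid run configuration."""


class ParseError(MpraError, ValueError):
    """Malformed file content; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
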