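"""Exception hierarchy for pedsel."""


class PedselError(Exception):
    """Base class for all pedsel errors."""


class ParseError(PedselError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(PedselError):
    """Input data violates a structural requirement (duplicates, cycles, ...)."""


class ConfigurationError(PedselError):
    """An analysis was configured inconsistently with its inputs."""


class InsufficientDataError(PedselError):
    """Too few observations to compute the requested statistic."""
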