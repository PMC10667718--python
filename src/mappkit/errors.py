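"""Exception hierarchy shared across the pipeline stages."""


class MappkitError(Exception):
    """Base class for all mappkit errors."""


class ConfigError(MappkitError):
    """Invalid or inconsistent configuration (bad paths, bad parameter values)."""


class ValidationError(MappkitError):
    """Input data violates a documented invariant."""


class SequenceModelError(ValidationError):
    """Invalid therapeutic definition (chains, CDR intervals, alphabet)."""


class PsmParseError(ValidationError):
    """Malformed PSM table row; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
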