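"""Exception hierarchy shared across the pipeline stages."""


class CtdnaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CtdnaError):
    """A parameter set violates its documented invariants."""


class InputError(CtdnaError):
    """An input table or file violates a precondition."""


class ParseError(InputError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SaturationError(CtdnaError):
    """All droplets positive: the Poisson estimate is undefined."""


class FitError(CtdnaError):
    """A statistical fit could not be carried out (e.g. no events)."""
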