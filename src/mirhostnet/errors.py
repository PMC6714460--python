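"""Exception hierarchy shared across the package."""


class MirHostNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirHostNetError, ValueError):
    """A scenario or analysis configuration is invalid or infeasible."""


class FormatError(MirHostNetError, ValueError):
    """An input file violates its expected format.

    Carries an optional 1-based ``line`` number pointing at the offending row.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
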