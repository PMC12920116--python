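"""Exception types shared across the package."""


class AavStructError(Exception):
    """Base class for package errors."""


class ConfigError(AavStructError):
    """Invalid configuration value or combination."""


class PanelSizeError(AavStructError):
    """Requested reference lengths below the supported minima."""


class ParseError(AavStructError):
    """Malformed record in an input file; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConsistencyError(AavStructError):
    """Inputs contradict each other (e.g. block beyond read length)."""


class EmptyInputError(AavStructError):
    """An operation that requires nonempty input received none."""


class PipelineError(AavStructError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
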