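"""Exception hierarchy for the pipeline."""


class BovitfError(Exception):
    """Base class for all package errors."""


class FormatError(BovitfError):
    """A file does not conform to its declared tabular format."""


class RowError(FormatError):
    """A single row is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(BovitfError):
    """Record-level semantic constraint violated."""


class ConfigError(BovitfError):
    """Inconsistent or incomplete configuration."""


class StageError(BovitfError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
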