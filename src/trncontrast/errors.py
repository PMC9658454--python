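"""Exception hierarchy for the pipeline.

Invalid arguments raise plain :class:`ValueError` and missing genes raise
:class:`KeyError`; the classes below mark failures that deserve a distinct
catch site in the pipeline driver.
"""


class TrnContrastError(Exception):
    """Base class for package-specific failures."""


class ParseError(TrnContrastError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class NormalizationError(TrnContrastError):
    """Size-factor normalization is undefined for the given matrix."""


class ConfigurationError(TrnContrastError):
    """The pipeline configuration is incomplete or inconsistent."""


class StageError(TrnContrastError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
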