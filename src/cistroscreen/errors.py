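"""Exception hierarchy shared across the package."""


class CistroscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CistroscreenError, ValueError):
    """Malformed record in an input file; message names the offending line."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


class ConfigError(CistroscreenError, ValueError):
    """Invalid parameter or configuration value."""


class CapacityError(CistroscreenError, ValueError):
    """Synthetic genome too small to place the requested gene count."""


class CalibrationError(CistroscreenError, ValueError):
    """Positive and negative control q-values are not separable."""


class DataError(CistroscreenError, ValueError):
    """Semantically invalid data (negative frequencies, bad labels, ...)."""


class PipelineError(CistroscreenError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
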