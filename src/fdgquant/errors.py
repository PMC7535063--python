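"""Exception hierarchy shared across the package."""


class FdgQuantError(Exception):
    """Base class for all package-specific errors."""


class InputError(FdgQuantError, ValueError):
    """Invalid numerical input (unsorted times, non-positive dose, ...)."""


class FormatError(FdgQuantError, ValueError):
    """Malformed on-disk table (bad header, overlapping frames, ...)."""


class ConfigError(FdgQuantError, ValueError):
    """Invalid configuration (bad window, coarse grid, missing region, ...)."""


class PipelineError(FdgQuantError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
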