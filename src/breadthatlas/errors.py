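"""Exception types shared across the pipeline."""


class BreadthAtlasError(Exception):
    """Base class for all package errors."""


class ConfigError(BreadthAtlasError, ValueError):
    """Invalid configuration value or combination."""


class InputError(BreadthAtlasError, ValueError):
    """Malformed or empty input data."""


class FormatError(InputError):
    """A file does not follow the expected layout (missing columns etc.)."""


class AnnotationError(InputError):
    """Structurally invalid gene annotation (overlapping exons, bad spans)."""


class SizingError(ConfigError):
    """A simulated layout cannot fit (e.g. genes longer than the genome)."""


class PipelineError(BreadthAtlasError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
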