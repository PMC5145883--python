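"""Typed errors raised across the pipeline.

Every malformed input raises one of these; no stage falls back to a
silent default.
"""


class StressModesError(Exception):
    """Base class for all package errors."""


class ParseError(StressModesError):
    """A file could not be parsed (names the offending line where known)."""


class ValidationError(StressModesError):
    """An input violates a data-model invariant."""


class ConfigError(StressModesError):
    """A configuration value is out of its admissible range."""


class NormalizationError(StressModesError):
    """Size-factor normalization is impossible for this matrix."""


class PipelineError(StressModesError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
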