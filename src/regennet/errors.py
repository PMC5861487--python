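"""Exception hierarchy shared across the pipeline stages."""


class RegenNetError(Exception):
    """Base class for all regennet errors."""


class FormatError(RegenNetError, ValueError):
    """Malformed input file (bad column layout, non-numeric cell, NA token)."""


class DesignError(RegenNetError, ValueError):
    """Sampling design incompatible with the requested operation."""


class DegenerateSampleError(RegenNetError, ValueError):
    """A sample column cannot be normalized (non-positive percentile)."""


class ParameterError(RegenNetError, ValueError):
    """An operation parameter is out of its documented range."""


class GenerationError(RegenNetError, RuntimeError):
    """Synthetic-model generation failed (e.g. stability guard unsatisfiable)."""


class PipelineError(RegenNetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
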