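"""Named exception types used across the pipeline."""


class SagradError(Exception):
    """Base class for all package errors."""


class ConfigValidationError(SagradError, ValueError):
    """A configuration value violates an invariant (bad fraction, geometry, ...)."""


class DegenerateSampleError(SagradError):
    """A sample's amplification weight vector is all zero; no reads can be drawn."""


class FastqFormatError(SagradError):
    """Malformed FASTQ input, including mate-count mismatches between read files."""


class UndefinedMetricError(SagradError):
    """A metric is undefined for this input (e.g. Gini of all-zero depths)."""


class PipelineStageError(SagradError):
    """A pipeline stage failed; carries the stage name and the underlying error."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
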