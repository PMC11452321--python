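"""Exception hierarchy shared by all pipeline stages."""


class OabnetError(Exception):
    """Base class for all errors raised by oabnet."""


class ConfigurationError(OabnetError):
    """An invalid generator or pipeline configuration."""


class FormatError(OabnetError):
    """An input table does not conform to a supported CSV dialect."""


class ValidationError(OabnetError):
    """Data violates an instrument or model invariant (bounds, sums, labels)."""


class ConstantVectorError(OabnetError):
    """Pearson correlation is undefined because a score vector is constant."""


class ConvergenceError(OabnetError):
    """An iterative solver failed to converge within its iteration budget."""

    def __init__(self, message: str, iterations: int | None = None):
        super().__init__(message)
        self.iterations = iterations


class PipelineStageError(OabnetError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
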