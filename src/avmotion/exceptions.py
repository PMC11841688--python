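"""Typed errors shared across avmotion modules."""


class ValidationError(ValueError):
    """Invalid input to an avmotion operation."""


class NotApplicableError(ValidationError):
    """The requested closed form or operation does not apply to these inputs."""


class UnidentifiableDataError(ValidationError):
    """Response data carry no information about the psychometric parameters
    (e.g. every response identical)."""


class InconsistentSharedNoiseError(ValidationError):
    """Shared-noise variance implies a cue correlation >= 1, i.e. shared noise
    exceeding at least one cue's total noise."""


class NegativeImageVarianceError(ValidationError):
    """Variance-sum-law subtraction left a non-positive image variance."""
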