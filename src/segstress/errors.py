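"""Exception hierarchy shared across the toolkit."""


class SegStressError(Exception):
    """Base class for all toolkit errors."""


class FormatError(SegStressError):
    """A file could not be read as a supported volume format."""


class ValidationError(SegStressError):
    """Inputs violate a documented precondition."""


class DegenerateMaskError(ValidationError):
    """A mask (or ROI) is empty or collapses under the requested operation."""


class SamplingFailureError(SegStressError):
    """Mask perturbation could not produce a valid sample within the
    configured attempt budget; usually a tolerance/smoothness mismatch."""


class UndefinedEffectError(SegStressError):
    """An effect-size denominator (pooled SD or between-patient IQR) is zero."""


class FitError(SegStressError):
    """A survival-model fit failed to converge."""
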