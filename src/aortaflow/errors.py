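"""Exception hierarchy.

All loader/validation failures derive from :class:`ValidationError` so callers
can catch one class, while tests can assert the specific failure mode.
"""


class AortaflowError(Exception):
    """Base class for all package errors."""


class ValidationError(AortaflowError):
    """An input violated a container invariant."""


class ShapeMismatchError(ValidationError):
    """Image stacks, masks, or sidecar metadata disagree on geometry."""


class MetadataError(ValidationError):
    """A sidecar or table is missing a required key/column or has a bad value."""


class TriggerTimeError(ValidationError):
    """Trigger times are non-monotone or exceed the RR interval."""


class MaskError(ValidationError):
    """A lumen mask frame is empty or malformed."""


class LandmarkError(AortaflowError):
    """Systolic landmarks could not be determined (e.g. no zero crossing)."""


class CurveError(AortaflowError):
    """A flow curve does not support the requested measurement."""


class ParameterError(AortaflowError):
    """A simulation or analysis parameter set is infeasible."""


class SeparationError(AortaflowError):
    """Logistic fit failed to converge (perfect/quasi separation)."""
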