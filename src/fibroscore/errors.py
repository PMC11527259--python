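"""Exception hierarchy.

All validation failures derive from :class:`ValidationError` (a ``ValueError``)
so callers can catch one type; more specific subclasses name the failing stage.
"""


class FibroscoreError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FibroscoreError, ValueError):
    """An input violated a documented precondition; the message names the field."""


class SamplingError(FibroscoreError):
    """Patch sampling found no eligible position."""


class ConversionError(FibroscoreError):
    """Raster-to-store conversion failed (typically missing resolution metadata)."""


class DimensionError(ValidationError):
    """A matrix or vector had the wrong width/length."""


class DataError(FibroscoreError):
    """Inconsistent keyed data (e.g. a biopsy mapped to two subjects)."""


class FitError(FibroscoreError):
    """A model fit could not proceed (degenerate outcome, too few repeats)."""


class UndefinedKappaError(FibroscoreError):
    """Cohen's kappa is undefined because expected agreement equals 1."""


class ProvisioningError(FibroscoreError):
    """A required local model file is absent; nothing is ever downloaded."""


class PipelineError(FibroscoreError):
    """A pipeline stage failed; the message names the stage."""
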