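"""Exception hierarchy.

All package errors derive from :class:`DissolvisError` so callers (and the
CLI) can distinguish validation problems (exit code 2) from stage failures
(exit code 3).
"""


class DissolvisError(Exception):
    """Base class for all package errors."""


class ValidationError(DissolvisError):
    """Invalid input data or configuration."""


class PhantomError(DissolvisError):
    """Synthetic phantom could not be constructed as requested."""


class SegmentationError(DissolvisError):
    """Segmentation produced an empty or degenerate result."""


class RegistrationError(DissolvisError):
    """Rigid registration failed (correlation below the configured floor)."""


class FitError(DissolvisError):
    """A model fit (Gaussian, calibration) failed to converge."""


class StageError(DissolvisError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
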