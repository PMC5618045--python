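"""Exception hierarchy for the sicklescreen pipeline.

Every error raised by the library derives from :class:`SickleScreenError`,
so callers (including the CLI) can distinguish pipeline failures from
programming errors.
"""


class SickleScreenError(Exception):
    """Base class for all sicklescreen errors."""


class ConfigurationError(SickleScreenError):
    """Unknown formulation, storage condition, or invalid configuration."""


class RenderError(SickleScreenError):
    """Stain geometry or render parameters violate their invariants."""


class FormatError(SickleScreenError):
    """Image file is missing, corrupt, or not 3-channel 8/16-bit raster."""


class SegmentationError(SickleScreenError):
    """Stain segmentation failed to produce valid center/ring masks."""


class NoStainFound(SegmentationError):
    """No connected foreground component of sufficient area."""


class AmbiguousStain(SegmentationError):
    """Multiple comparable foreground components."""


class DegenerateInputError(SickleScreenError):
    """Input is degenerate (e.g. zero ring intensity, both volumes zero)."""


class ValidationError(SickleScreenError):
    """Data table or domain object violates a structural invariant."""


class InfeasibleTargetError(SickleScreenError):
    """Requested mixture target cannot be reached with the given components."""
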