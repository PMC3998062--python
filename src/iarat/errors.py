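"""Exception hierarchy shared across the package."""


class IaratError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IaratError):
    """A file does not conform to the documented CSV dialect."""


class ValidationError(IaratError):
    """A recording violates a physical or structural invariant."""


class ParameterError(IaratError):
    """An argument is outside its admissible range."""


class SegmentationError(IaratError):
    """A task recording cannot be decomposed into the requested sub-movements."""


class PhaseBelowThresholdError(SegmentationError):
    """The angular-speed profile never exceeds the threshold inside a window."""

    def __init__(self, window_id, message=None):
        self.window_id = window_id
        super().__init__(message or f"phase_below_threshold in window {window_id!r}")


class UndefinedMetricError(IaratError):
    """A metric is undefined for the given window (e.g. zero mean acceleration)."""


class DegenerateNormativeError(IaratError):
    """Control statistics have zero spread for a cell that must be z-scored."""
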