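"""Exception types shared across the package."""


class CardionucError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(CardionucError):
    """Raised when a generator target cannot be met (e.g. gain ceiling)."""


class GeometryError(CardionucError):
    """Raised for infeasible geometry (nucleus outside grid, bad layering)."""


class SegmentationError(CardionucError):
    """Raised when no nucleus can be segmented from an image."""


class NoContractionDetected(CardionucError):
    """Raised when a strain trace never crosses the onset threshold."""


class InsufficientDataError(CardionucError):
    """Raised when a limb/segment has too few samples to integrate or fit."""


class ConfigError(CardionucError):
    """Raised for invalid run configurations or unknown presets/scenarios."""


class SolverError(CardionucError):
    """Raised when the finite-element solver fails to converge."""

    def __init__(self, message, last_converged=None):
        super().__init__(message)
        self.last_converged = last_converged
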