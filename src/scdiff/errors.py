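"""Exception hierarchy shared across the package."""


class ScDiffError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ScDiffError):
    """Invalid parameter combination (e.g. T not divisible by k)."""


class ContractError(ScDiffError):
    """Violated call contract (shape mismatch, off-grid time index, ...)."""


class GeometryError(ScDiffError):
    """Inconsistent image geometry (e.g. mixed-size DICOM series)."""


class FormatError(ScDiffError):
    """Unreadable or unsupported image file."""


class DivergenceError(ScDiffError):
    """Training produced a non-finite loss; carries last-good checkpoint."""

    def __init__(self, message, checkpoint_path=None):
        super().__init__(message)
        self.checkpoint_path = checkpoint_path


class DegenerateWeightsError(ScDiffError):
    """All-zero channel importances in the spatial reconstruction unit."""
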