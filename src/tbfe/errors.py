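"""Exception hierarchy for the tbfe package."""


class TbfeError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(TbfeError):
    """Raised when a HU-to-density calibration cannot be fitted."""


class UnitError(TbfeError):
    """Raised when a volume's units tag does not match the requested conversion."""


class MeshError(TbfeError):
    """Raised for invalid or degenerate voxel meshes."""


class BoundaryError(MeshError):
    """Raised when loading surfaces cannot be defined (e.g. single-layer mesh)."""


class MaterialError(TbfeError):
    """Raised for invalid constitutive parameters."""


class SolverError(TbfeError):
    """Base class for finite-element solve failures."""


class ConvergenceError(SolverError):
    """Newton iteration failed to converge; carries the last residual norm."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class AnchoringError(SolverError):
    """Stiffness matrix singular: mesh contains components not anchored at the bottom."""


class SegmentationError(TbfeError):
    """Raised when bone segmentation produces an empty or degenerate mask."""


class VoiError(TbfeError):
    """Raised when VOI selection yields an empty region."""


class AnalysisError(TbfeError):
    """Raised for degenerate post-processing inputs (empty regions, zero fields...)."""


class ConfigError(TbfeError):
    """Raised for invalid configuration values."""
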