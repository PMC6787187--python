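"""Exception hierarchy shared across the package."""


class AsaMeshError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(AsaMeshError, ValueError):
    """A layout or grid does not fit the requested substrate."""


class GeometryError(AsaMeshError, ValueError):
    """Invalid or inconsistent geometric input."""


class ClassificationError(AsaMeshError, ValueError):
    """Pillar classification is not defined for this layout."""


class UnsupportedLatticeError(AsaMeshError, ValueError):
    """Operation not defined for this lattice kind."""


class RefinementError(AsaMeshError, ValueError):
    """Requested element size is too coarse for the geometry."""


class KinematicsError(AsaMeshError, ValueError):
    """Singular or inverted deformation state."""


class InvertedElementError(KinematicsError):
    """An element Jacobian became non-positive (J <= 0)."""


class IncompressibilityError(AsaMeshError, ValueError):
    """nu = 0.5 requested: the first Lame parameter diverges."""


class ThicknessSolveError(AsaMeshError, RuntimeError):
    """Plane-stress thickness root not found in the search bracket."""


class ConvergenceError(AsaMeshError, RuntimeError):
    """Newton iteration failed to converge after step bisection."""


class ContactStiffnessError(AsaMeshError, RuntimeError):
    """Penetration exceeded tolerance even after penalty escalation."""


class SegmentationError(AsaMeshError, ValueError):
    """Degenerate input to automatic thresholding."""


class QuantificationError(AsaMeshError, ValueError):
    """Undefined image statistic (e.g. empty ROI or zero vessels)."""


class PlacementError(AsaMeshError, RuntimeError):
    """Hard-core vessel placement could not fit the requested scene."""


class ConfigError(AsaMeshError, ValueError):
    """Schema violation in a run configuration file."""
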