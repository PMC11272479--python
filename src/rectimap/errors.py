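"""Exception hierarchy shared across the package."""


class RectimapError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(RectimapError):
    """A mesh file could not be parsed, or violates mesh invariants."""


class DegenerateAxisError(RectimapError):
    """Principal axis is undefined (near-isotropic vertex cloud)."""


class TopologyError(RectimapError):
    """A plane section produced an open contour that cannot be chained."""


class EmptySectionError(RectimapError):
    """A cutting plane does not intersect the mesh."""


class LandmarkError(RectimapError):
    """A required named landmark is missing or duplicated."""


class RegionError(RectimapError):
    """A rectification region mask is missing, empty or mostly unmeasured."""


class AlignmentError(RectimapError):
    """Coarse or fine alignment cannot proceed (bad mask, bad landmarks)."""


class CohortError(RectimapError):
    """Cohort table fails validation or a statistic cannot be formed."""


class ModelError(RectimapError):
    """KDE / Naive Bayes fitting failed (degenerate data, empty class)."""
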