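"""Signed rectification maps and the eight socket design variables.

A socket's design is summarised relative to the limb scan it was made for:

* a **deviation map** — for every limb vertex, the signed distance along the
  vertex normal to the aligned socket surface.  Positive deviations mean the
  socket lies inside the limb (a *carve*: material removed from the mould so
  the socket presses in); negative deviations mean the socket lies outside
  (a *build*: relief added).
* seven **local rectification sizes** (PT, FH, MP, LP, TC, DE, LMC, in mm) —
  the 98th-percentile deviation over each region's vertex cluster, oriented
  so the region's expected direction is positive.  The 98th percentile is
  used instead of the maximum to suppress single-vertex noise.
* a global **volume reduction** (VR, %) — the mean relative cross-sectional
  area difference between limb and socket over 10 sections spanning the
  mid-patellar-tendon to distal-tibia axial levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import RegionError, RectimapError
from .geometry import ray_offsets_along_normals
from .mesh import (
    LandmarkSet,
    RegionMaskSet,
    SurfaceMesh,
    cross_section_area,
    principal_axis,
)

__all__ = [
    "DeviationMap",
    "RectificationProfile",
    "compute_deviation_map",
    "region_size",
    "volume_reduction",
    "extract_profile",
    "PROFILE_VARIABLES",
]

#: Canonical variable order used in tables and CSV columns.
PROFILE_VARIABLES = ("PT", "FH", "MP", "LP", "TC", "DE", "LMC", "VR")

#: CSV column names for the eight design variables.
PROFILE_COLUMNS = ("PT_mm", "FH_mm", "MP_mm", "LP_mm", "TC_mm", "DE_mm",
                   "LMC_mm", "VR_pct")


@dataclass
class DeviationMap:
    """Per-limb-vertex signed limb-to-socket distance (mm).

    ``values[i]`` is NaN where ``missing[i]`` is True (no socket surface
    found within the search cutoff along the vertex normal).
    Sign convention: positive = carve, negative = build.
    """

    values: np.ndarray
    missing: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing must have identical shape")
        if np.any(~np.isfinite(self.values[~self.missing])):
            raise ValueError("non-missing deviations must be finite")


@dataclass
class RectificationProfile:
    """The eight design variables of one socket.

    Local sizes are non-negative magnitudes in each region's expected
    direction (mm); VR is a percentage and may be negative only when the
    socket is globally larger than the limb (``oversized`` flag).
    """

    PT: float
    FH: float
    MP: float
    LP: float
    TC: float
    DE: float
    LMC: float
    VR: float
    socket_id: str | None = None
    design_label: str | None = None
    raw_region_values: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in PROFILE_VARIABLES[:-1]:
            if getattr(self, name) < 0:
                raise ValueError(f"region size {name} must be non-negative")

    @property
    def oversized(self) -> bool:
        return self.VR < 0

    def as_dict(self) -> dict:
        d = {col: float(getattr(self, var))
             for var, col in zip(PROFILE_VARIABLES, PROFILE_COLUMNS)}
        d["socket_id"] = self.socket_id
        d["design_label"] = self.design_label
        return d

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, v) for v in PROFILE_VARIABLES], dtype=float)


def compute_deviation_map(
    limb: SurfaceMesh,
    socket_aligned: SurfaceMesh,
    cutoff: float = 50.0,
) -> DeviationMap:
    """Signed limb-to-socket deviation along each limb vertex normal.

    For every limb vertex a ray is cast along its outward normal in both
    directions; the nearest socket intersection within ``cutoff`` mm gives
    the deviation, positive when the socket point lies inward of the limb
    vertex (carve).  Vertices without an intersection are marked missing and
    excluded from region statistics.
    """
    t, hit = ray_offsets_along_normals(
        socket_aligned.triangle_set,
        limb.vertices,
        limb.vertex_normals,
        cutoff=cutoff,
    )
    if not hit.any():
        raise RectimapError(
            "meshes appear disjoint: no limb vertex sees the socket within "
            f"{cutoff} mm"
        )
    # socket at +t along the outward normal => outside the limb => build (<0)
    values = np.where(hit, -t, np.nan)
    return DeviationMap(values=values, missing=~hit)


def region_size(
    dev_map: DeviationMap,
    mask_vertices: np.ndarray,
    direction: str,
    min_vertices: int = 10,
    max_missing_fraction: float = 0.5,
    region_name: str = "?",
) -> tuple[float, float]:
    """Size of one rectification region, mm.

    Signed deviations over the mask are oriented so the expected direction
    is positive (carve: +map, build: -map); the 98th percentile (linear
    interpolation between order statistics) is returned, floored at zero.
    The raw signed percentile is returned alongside for diagnostics.
    """
    if direction not in ("carve", "build"):
        raise ValueError(f"direction must be carve|build, got {direction!r}")
    idx = np.asarray(mask_vertices, dtype=np.int64)
    if idx.size == 0:
        raise RegionError(f"region {region_name!r}: empty mask")
    miss = dev_map.missing[idx]
    if miss.mean() > max_missing_fraction:
        raise RegionError(
            f"region {region_name!r}: {miss.mean():.0%} of mask vertices have "
            "no measurable deviation"
        )
    d = dev_map.values[idx][~miss]
    if d.size < min_vertices:
        raise RegionError(
            f"region {region_name!r}: only {d.size} measurable vertices "
            f"(minimum {min_vertices})"
        )
    if direction == "build":
        d = -d
    raw = float(np.percentile(d, 98))
    return max(raw, 0.0), raw


def volume_reduction(
    limb: SurfaceMesh,
    socket_aligned: SurfaceMesh,
    landmarks: LandmarkSet,
    n_sections: int = 10,
) -> float:
    """Global volume reduction, percent.

    Ten planes perpendicular to the limb's principal axis are spaced equally
    (inclusive endpoints) between the axial levels of the mid-patellar-tendon
    and distal-tibia landmarks; VR is the mean over sections of
    ``(A_limb - A_socket) / A_limb * 100``.
    """
    axis, centroid = principal_axis(limb)
    lo = float((landmarks["mid_patellar_tendon"] - centroid) @ axis)
    hi = float((landmarks["distal_tibia"] - centroid) @ axis)
    levels = np.linspace(lo, hi, n_sections)
    ratios = []
    for lev in levels:
        point = centroid + lev * axis
        try:
            a_limb = cross_section_area(limb, point, axis)
            a_sock = cross_section_area(socket_aligned, point, axis)
        except RectimapError as exc:
            raise RectimapError(
                f"empty or invalid section at axial level {lev:.2f} mm: {exc}"
            ) from exc
        ratios.append((a_limb - a_sock) / a_limb)
    return float(np.mean(ratios) * 100.0)


def extract_profile(
    limb: SurfaceMesh,
    socket_aligned: SurfaceMesh,
    landmarks: LandmarkSet,
    masks: RegionMaskSet,
    socket_id: str | None = None,
    design_label: str | None = None,
    cutoff: float = 50.0,
) -> tuple[RectificationProfile, DeviationMap]:
    """All eight design variables of an aligned limb/socket pair.

    Runs :func:`compute_deviation_map`, :func:`region_size` for the seven
    regions and :func:`volume_reduction`, returning the profile together
    with the deviation map (for rendering/export).
    """
    masks.validate_for(limb)
    dev = compute_deviation_map(limb, socket_aligned, cutoff=cutoff)
    sizes = {}
    raw = {}
    from .mesh import REGION_DIRECTIONS

    for name, direction in REGION_DIRECTIONS.items():
        if name not in masks:
            raise RegionError(f"region {name!r} missing from mask set")
        sizes[name], raw[name] = region_size(
            dev, masks[name], direction, region_name=name
        )
    vr = volume_reduction(limb, socket_aligned, landmarks)
    profile = RectificationProfile(
        **sizes, VR=vr, socket_id=socket_id, design_label=design_label,
        raw_region_values=raw,
    )
    return profile, dev
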