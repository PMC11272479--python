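"""Two-stage limb/socket alignment.

The socket mould is mapped into the limb frame in two stages, mirroring
common clinical shape-analysis practice: a coarse alignment from the
principal axes and two picked landmarks (mid patella, distal tibia), then a
point-to-surface iterative closest point (ICP) refinement restricted to the
anterior, sub-patellar portion of the limb — the region least affected by
rectification, so it anchors the registration.  An optional override
transform stands in for manual expert adjustment of the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError
from .geometry import TriangleSet, closest_point_on_surface, kabsch
from .mesh import LandmarkSet, RigidTransform, SurfaceMesh, apply_transform, principal_axis

__all__ = ["coarse_align", "icp_align", "align_pair", "ICPResult", "AlignmentResult"]

_COARSE_LANDMARKS = ("mid_patella", "distal_tibia")


@dataclass
class ICPResult:
    transform: RigidTransform
    rms: float
    iterations: int
    converged: bool
    rms_trace: list = field(default_factory=list)


@dataclass
class AlignmentResult:
    """Composite transform mapping the socket into the limb frame, with
    per-stage diagnostics."""

    transform: RigidTransform
    coarse: RigidTransform
    coarse_rms: float
    icp: ICPResult | None
    override: RigidTransform | None


def coarse_align(
    limb: SurfaceMesh,
    socket: SurfaceMesh,
    limb_landmarks: LandmarkSet,
    socket_landmarks: LandmarkSet,
) -> tuple[RigidTransform, float]:
    """Coarse socket-to-limb transform from principal axes and landmarks.

    A single Kabsch fit over four correspondences — the two centroids, a
    point offset along each principal axis (which aligns the axes), and the
    mid-patella and distal-tibia landmark pairs — resolves rotation about
    the axis and translation in one least-squares step.

    Returns the transform and the residual RMS (mm) over the four
    correspondences after alignment.
    """
    axis_l, cent_l = principal_axis(limb)
    axis_s, cent_s = principal_axis(socket)
    for name in _COARSE_LANDMARKS:
        if name not in limb_landmarks.points or name not in socket_landmarks.points:
            raise AlignmentError(f"landmark {name!r} required for coarse alignment")
    # length scale for the axis pseudo-points: half the limb's axial extent
    proj = (limb.vertices - cent_l) @ axis_l
    h = 0.5 * (proj.max() - proj.min())
    src = np.array([
        cent_s,
        cent_s + h * axis_s,
        socket_landmarks["mid_patella"],
        socket_landmarks["distal_tibia"],
    ])
    dst = np.array([
        cent_l,
        cent_l + h * axis_l,
        limb_landmarks["mid_patella"],
        limb_landmarks["distal_tibia"],
    ])
    R, t = kabsch(src, dst)
    T = RigidTransform(R, t)
    rms = float(np.sqrt(np.mean(np.sum((T.apply(src) - dst) ** 2, axis=1))))
    return T, rms


def icp_align(
    limb: SurfaceMesh,
    socket: SurfaceMesh,
    anterior_mask: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-4,
    max_pair_distance: float | None = None,
) -> ICPResult:
    """Point-to-surface ICP of the socket onto the limb's anterior mask.

    Each iteration matches every masked limb vertex to its nearest point on
    the (current) socket surface — point-to-triangle, not vertex-to-vertex —
    solves the Kabsch transform over the pairs and applies it to the socket.
    Iteration stops when the RMS improvement drops below ``tol`` (mm) or
    after ``max_iter`` iterations; non-convergence is reported via the
    ``converged`` flag, not an exception.

    ``max_pair_distance`` optionally discards matches farther than the given
    cutoff (off by default; the core method uses all pairs).
    """
    anterior_mask = np.asarray(anterior_mask, dtype=np.int64)
    if anterior_mask.size == 0:
        raise AlignmentError("anterior mask is empty")
    limb_pts = limb.vertices[anterior_mask]
    cumulative = RigidTransform.identity()
    if max_iter == 0:
        return ICPResult(cumulative, float("nan"), 0, False, [])
    verts = socket.vertices.copy()
    trace: list[float] = []
    prev_rms = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        triset = TriangleSet(verts, socket.faces)
        closest, dist, _ = closest_point_on_surface(triset, limb_pts)
        if max_pair_distance is not None:
            keep = dist <= max_pair_distance
            if keep.sum() < 3:
                raise AlignmentError("fewer than 3 ICP pairs under max_pair_distance")
        else:
            keep = slice(None)
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        trace.append(rms)
        if prev_rms - rms < tol:
            converged = True
            break
        R, t = kabsch(closest[keep], limb_pts[keep])
        step = RigidTransform(R, t)
        verts = step.apply(verts)
        cumulative = step.compose(cumulative)
        prev_rms = rms
    return ICPResult(cumulative, trace[-1], it, converged, trace)


def align_pair(
    limb: SurfaceMesh,
    socket: SurfaceMesh,
    limb_landmarks: LandmarkSet,
    socket_landmarks: LandmarkSet,
    anterior_mask: np.ndarray,
    override: RigidTransform | None = None,
    max_iter: int = 50,
    tol: float = 1e-4,
    max_pair_distance: float | None = None,
) -> AlignmentResult:
    """Full socket-to-limb registration: coarse, then ICP, then override.

    The returned transform is ``override ∘ icp ∘ coarse`` (socket frame to
    limb frame).  The override slot is a deterministic replacement for
    manual inspection-and-adjustment of the registration.
    """
    coarse_T, coarse_rms = coarse_align(limb, socket, limb_landmarks, socket_landmarks)
    socket_c = apply_transform(socket, coarse_T)
    icp_res = icp_align(limb, socket_c, anterior_mask, max_iter=max_iter,
                        tol=tol, max_pair_distance=max_pair_distance)
    total = icp_res.transform.compose(coarse_T)
    if override is not None:
        total = override.compose(total)
    return AlignmentResult(total, coarse_T, coarse_rms, icp_res, override)
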