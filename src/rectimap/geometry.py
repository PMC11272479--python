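"""Low-level vectorised geometry kernels.

Closest-point-on-surface and ray-surface queries are implemented here with
numpy over cKDTree candidate sets.  Both use triangle-centroid KD-trees to
shortlist candidate triangles per query point, then evaluate the exact
point-triangle / ray-triangle primitive on the shortlist.  For the smooth,
roughly uniformly meshed surfaces this package works with (limb scans and
socket moulds), a shortlist of a few dozen nearest centroids always contains
the true nearest triangle.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "kabsch",
    "TriangleSet",
    "closest_point_on_surface",
    "ray_offsets_along_normals",
]


def kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping ``source`` onto ``target``.

    Standard SVD solution with the determinant sign fix so that R is a
    proper rotation.  Points are (n, 3); n >= 3 non-collinear points are
    required for a unique rotation.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    cs = source.mean(axis=0)
    ct = target.mean(axis=0)
    H = (source - cs).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cs
    return R, t


class TriangleSet:
    """Precomputed triangle arrays plus a centroid KD-tree for candidate lookup."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.v0 = vertices[faces[:, 0]]
        self.e1 = vertices[faces[:, 1]] - self.v0
        self.e2 = vertices[faces[:, 2]] - self.v0
        self.centroids = self.v0 + (self.e1 + self.e2) / 3.0
        self.tree = cKDTree(self.centroids)
        self.n = len(faces)

    def candidates(self, points: np.ndarray, k: int) -> np.ndarray:
        k = min(k, self.n)
        _, idx = self.tree.query(points, k=k)
        if k == 1:
            idx = idx[:, None]
        return idx


def _closest_on_triangles(p: np.ndarray, v0, e1, e2) -> np.ndarray:
    """Closest point on each triangle (broadcast over a trailing candidate axis).

    Ericson's real-time collision detection region test, vectorised.
    ``p`` is (n, 1, 3); triangle arrays are (n, k, 3).  Returns (n, k, 3).
    """
    ap = p - v0
    d1 = np.einsum("...i,...i", e1, ap)
    d2 = np.einsum("...i,...i", e2, ap)
    bp = p - (v0 + e1)
    d3 = np.einsum("...i,...i", e1, bp)
    d4 = np.einsum("...i,...i", e2, bp)
    cp = p - (v0 + e2)
    d5 = np.einsum("...i,...i", e1, cp)
    d6 = np.einsum("...i,...i", e2, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(np.abs(denom) > 0, vb / denom, 0.0)
        w = np.where(np.abs(denom) > 0, vc / denom, 0.0)
    # interior barycentric point, then clamp through the six exterior regions
    out = v0 + v[..., None] * e1 + w[..., None] * e2

    # edge AB region
    cond = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out = np.where(cond[..., None], v0 + t_ab[..., None] * e1, out)
    # edge AC region
    cond = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out = np.where(cond[..., None], v0 + t_ac[..., None] * e2, out)
    # edge BC region
    cond = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    out = np.where(cond[..., None], v0 + e1 + t_bc[..., None] * (e2 - e1), out)
    # vertex regions
    cond = (d1 <= 0) & (d2 <= 0)
    out = np.where(cond[..., None], v0, out)
    cond = (d3 >= 0) & (d4 <= d3)
    out = np.where(cond[..., None], v0 + e1, out)
    cond = (d6 >= 0) & (d5 <= d6)
    out = np.where(cond[..., None], v0 + e2, out)
    return out


def closest_point_on_surface(
    triset: TriangleSet, points: np.ndarray, k: int = 48
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest surface point for each query point.

    Returns ``(closest, distance, triangle_index)``.  Ties in the nearest
    triangle are broken toward the lowest triangle index (argmin semantics
    over the index-sorted candidate list).
    """
    points = np.asarray(points, dtype=float)
    idx = triset.candidates(points, k)
    idx = np.sort(idx, axis=1)  # deterministic tie-break: lowest index wins
    cp = _closest_on_triangles(
        points[:, None, :], triset.v0[idx], triset.e1[idx], triset.e2[idx]
    )
    d2 = np.sum((cp - points[:, None, :]) ** 2, axis=-1)
    best = np.argmin(d2, axis=1)
    rows = np.arange(len(points))
    return cp[rows, best], np.sqrt(d2[rows, best]), idx[rows, best]


def ray_offsets_along_normals(
    triset: TriangleSet,
    origins: np.ndarray,
    normals: np.ndarray,
    cutoff: float = 50.0,
    k: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed ray parameters of the nearest surface intersection along each normal.

    Casts the full line through each origin along its (unit) normal and
    returns, per origin, the intersection parameter ``t`` with the smallest
    magnitude (positive t = along +normal).  Origins whose nearest hit lies
    beyond ``cutoff`` mm, or that hit nothing among the candidate triangles,
    are flagged missing.

    Returns ``(t, hit)`` with ``t`` (n,) float (NaN where missing) and
    ``hit`` (n,) bool.
    """
    origins = np.asarray(origins, dtype=float)
    normals = np.asarray(normals, dtype=float)
    idx = triset.candidates(origins, k)
    v0 = triset.v0[idx]
    e1 = triset.e1[idx]
    e2 = triset.e2[idx]
    d = normals[:, None, :]
    o = origins[:, None, :]

    # Moller-Trumbore, full line (t may be negative)
    h = np.cross(d, e2)
    a = np.einsum("...i,...i", e1, h)
    parallel = np.abs(a) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(parallel, 0.0, 1.0 / np.where(parallel, 1.0, a))
    s = o - v0
    u = f * np.einsum("...i,...i", s, h)
    q = np.cross(s, e1)
    v = f * np.einsum("...i,...i", d, q)
    t = f * np.einsum("...i,...i", e2, q)
    eps = 1e-9
    valid = (~parallel) & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps)
    tt = np.where(valid, t, np.inf)
    order = np.argmin(np.abs(tt), axis=1)
    rows = np.arange(len(origins))
    tbest = tt[rows, order]
    hit = np.isfinite(tbest) & (np.abs(tbest) <= cutoff)
    tbest = np.where(hit, tbest, np.nan)
    return tbest, hit
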