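"""Mesh and landmark data types, STL/PLY I/O and basic geometry.

All lengths are millimetres, areas mm².  The canonical anatomical frame puts
the distal direction along +z; anterior is +x for synthetic limbs.  Meshes
may be open (limb scans are open proximally); only plane-section contours
are required to close.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import (
    DegenerateAxisError,
    EmptySectionError,
    LandmarkError,
    MeshFormatError,
    RegionError,
    TopologyError,
)
from .geometry import TriangleSet

REQUIRED_LANDMARKS = ("mid_patella", "mid_patellar_tendon", "distal_tibia")

#: The seven local rectification regions and their expected direction.
#: carve = material removed from the mould (socket presses into the limb),
#: build = material added (socket relieved away from the limb).
REGION_DIRECTIONS = {
    "PT": "carve",   # patellar tendon
    "FH": "build",   # fibular head
    "MP": "carve",   # medial paratibial
    "LP": "carve",   # lateral paratibial
    "TC": "build",   # tibial crest
    "DE": "build",   # distal end elongation
    "LMC": "carve",  # lateral-medial supracondylar
}

REGION_NAMES = tuple(REGION_DIRECTIONS)

_MERGE_TOL = 1e-9   # duplicate-vertex merge, mm
_CHAIN_TOL = 1e-6   # contour endpoint matching, mm


class SurfaceMesh:
    """Triangulated 3D surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    normals : optional (n, 3) outward unit vertex normals

    Zero-area faces are dropped at construction; non-finite coordinates or
    out-of-range indices raise :class:`MeshFormatError`.
    """

    def __init__(self, vertices, faces, normals=None):
        v = np.ascontiguousarray(vertices, dtype=float)
        f = np.ascontiguousarray(faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or len(v) == 0:
            raise MeshFormatError("vertices must be a non-empty (n, 3) array")
        if not np.isfinite(v).all():
            bad = int(np.argwhere(~np.isfinite(v).all(axis=1))[0, 0])
            raise MeshFormatError(f"non-finite coordinate at vertex {bad}")
        if f.ndim != 2 or f.shape[1] != 3 or len(f) == 0:
            raise MeshFormatError("faces must be a non-empty (m, 3) array")
        if f.min() < 0 or f.max() >= len(v):
            raise MeshFormatError("face index out of range")
        areas = 0.5 * np.linalg.norm(
            np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1
        )
        f = f[areas > 1e-12]
        if len(f) == 0:
            raise MeshFormatError("all faces are degenerate (zero area)")
        self.vertices = v
        self.faces = f
        if normals is not None:
            normals = np.ascontiguousarray(normals, dtype=float)
            norms = np.linalg.norm(normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise MeshFormatError("supplied normals are not unit length")
        self._normals = normals
        self._triset = None

    # -- derived quantities -------------------------------------------------

    @property
    def vertex_normals(self) -> np.ndarray:
        """Outward unit vertex normals (area-weighted face-normal average)."""
        if self._normals is None:
            fn = np.cross(
                self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]],
                self.vertices[self.faces[:, 2]] - self.vertices[self.faces[:, 0]],
            )  # length = 2 * area, i.e. already area-weighted
            acc = np.zeros_like(self.vertices)
            for col in range(3):
                np.add.at(acc, self.faces[:, col], fn)
            n = np.linalg.norm(acc, axis=1)
            n[n == 0] = 1.0
            self._normals = acc / n[:, None]
        return self._normals

    @property
    def triangle_set(self) -> TriangleSet:
        if self._triset is None:
            self._triset = TriangleSet(self.vertices, self.faces)
        return self._triset

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def __repr__(self):  # pragma: no cover
        return f"SurfaceMesh({len(self.vertices)} vertices, {len(self.faces)} faces)"


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t (rotation 3x3, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9 or abs(np.linalg.det(R) - 1) > 1e-9:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg, translation=(0, 0, 0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        a = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def angle_deg(self) -> float:
        """Rotation magnitude in degrees."""
        c = np.clip((np.trace(self.rotation) - 1) / 2, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


@dataclass
class LandmarkSet:
    """Named anatomical points, mm.

    Required names: ``mid_patella``, ``mid_patellar_tendon``, ``distal_tibia``.
    """

    points: dict = field(default_factory=dict)

    def __post_init__(self):
        pts = {}
        for name, p in self.points.items():
            p = np.asarray(p, dtype=float).reshape(3)
            if not np.isfinite(p).all():
                raise LandmarkError(f"landmark {name!r} has non-finite coordinates")
            pts[name] = p
        for name in REQUIRED_LANDMARKS:
            if name not in pts:
                raise LandmarkError(f"required landmark {name!r} missing")
        self.points = pts

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def transformed(self, T: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({k: T.apply(v) for k, v in self.points.items()})

    def to_json(self, path):
        Path(path).write_text(
            json.dumps({k: list(map(float, v)) for k, v in self.points.items()},
                       indent=2)
        )

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        return cls(json.loads(Path(path).read_text()))


@dataclass
class RegionMaskSet:
    """Region-name -> limb vertex indices for the seven rectification regions.

    Indices are 0-based into the associated limb mesh.  Directions are fixed
    by :data:`REGION_DIRECTIONS` and not user-settable.
    """

    masks: dict = field(default_factory=dict)

    def __post_init__(self):
        out = {}
        for name, idx in self.masks.items():
            if name not in REGION_DIRECTIONS:
                raise RegionError(f"unknown region name {name!r}")
            out[name] = np.unique(np.asarray(idx, dtype=np.int64))
        self.masks = out

    def validate_for(self, mesh: SurfaceMesh):
        for name, idx in self.masks.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= len(mesh.vertices)):
                raise RegionError(f"region {name!r} has out-of-range vertex indices")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def direction(self, name: str) -> str:
        return REGION_DIRECTIONS[name]

    def to_json(self, path):
        Path(path).write_text(
            json.dumps({k: v.tolist() for k, v in self.masks.items()})
        )

    @classmethod
    def from_json(cls, path) -> "RegionMaskSet":
        return cls(json.loads(Path(path).read_text()))


# -- I/O ---------------------------------------------------------------------

def _merge_duplicate_vertices(v: np.ndarray, f: np.ndarray):
    """Merge vertices closer than _MERGE_TOL so faces share indices."""
    key = np.round(v / max(_MERGE_TOL, 1e-12)).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)        # keep original vertex order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return v[np.sort(first)], rank[inverse][f]


def read_mesh(path, fmt: str | None = None) -> SurfaceMesh:
    """Read an STL (ASCII or binary) or PLY file into a :class:`SurfaceMesh`.

    Duplicate vertices within 1e-9 mm are merged so that faces share indices
    (STL stores each triangle's corners independently).
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:
        raise MeshFormatError(f"cannot parse {path.name} as {fmt}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{path.name}: no triangulated surface found")
    v = np.asarray(tm.vertices, dtype=float)
    f = np.asarray(tm.faces, dtype=np.int64)
    if not np.isfinite(v).all():
        bad = int(np.argwhere(~np.isfinite(v).all(axis=1))[0, 0])
        raise MeshFormatError(f"{path.name}: non-finite coordinate at record {bad}")
    v, f = _merge_duplicate_vertices(v, f)
    return SurfaceMesh(v, f)


def write_mesh(mesh: SurfaceMesh, path, fmt: str | None = None) -> None:
    """Write a mesh as STL or PLY; round-trips through :func:`read_mesh`."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    mesh.to_trimesh().export(str(path), file_type=fmt)


def write_deviation_ply(mesh: SurfaceMesh, scalars: np.ndarray, path) -> None:
    """Export a mesh with a per-vertex scalar (``quality``) as ASCII PLY."""
    scalars = np.asarray(scalars, dtype=float)
    v, f = mesh.vertices, mesh.faces
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(v)}",
        "property float x", "property float y", "property float z",
        "property float quality",
        f"element face {len(f)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for p, s in zip(v, scalars):
        lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {0.0 if np.isnan(s) else s:.6f}")
    for tri in f:
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- basic geometry ----------------------------------------------------------

def principal_axis(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Dominant axis of the vertex cloud and its centroid.

    The axis is the covariance eigenvector with the largest eigenvalue,
    sign-fixed to point from mid-limb toward the vertex farthest from the
    centroid (the distal end for limb-like shapes).
    """
    v = mesh.vertices
    centroid = v.mean(axis=0)
    cov = np.cov((v - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or (evals[-1] - evals[-2]) / evals[-1] < 0.01:
        raise DegenerateAxisError(
            "largest two covariance eigenvalues within 1% — axis undefined"
        )
    axis = evecs[:, -1]
    # sign: point from mid-limb toward the vertex farthest from the centroid
    # along the axis (the distal tip for limb-like shapes)
    proj = (v - centroid) @ axis
    if abs(proj.min()) > abs(proj.max()):
        axis = -axis
    return axis, centroid


def apply_transform(mesh: SurfaceMesh, T: RigidTransform) -> SurfaceMesh:
    """Return a new mesh with every vertex mapped through ``T``; faces unchanged."""
    return SurfaceMesh(T.apply(mesh.vertices), mesh.faces.copy())


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    return u, np.cross(n, u)


def cross_section_area(mesh: SurfaceMesh, plane_point, plane_normal) -> float:
    """Area (mm²) of the mesh's cross-section with a plane.

    Triangle-plane intersection segments are chained into closed contours
    (endpoints matched within 1e-6 mm); the summed absolute shoelace area of
    all contours is returned.  Raises :class:`EmptySectionError` when the
    plane misses the mesh and :class:`TopologyError` when a contour fails to
    close.
    """
    plane_point = np.asarray(plane_point, dtype=float)
    plane_normal = np.asarray(plane_normal, dtype=float)
    segments = trimesh.intersections.mesh_plane(
        mesh.to_trimesh(), plane_normal=plane_normal, plane_origin=plane_point
    )
    if len(segments) == 0:
        raise EmptySectionError("plane does not intersect the mesh")
    # project endpoints into plane coordinates
    u, w = _plane_basis(plane_normal)
    pts = segments.reshape(-1, 3) - plane_point
    pts2 = np.column_stack([pts @ u, pts @ w])
    # cluster endpoints within the chaining tolerance
    tree = cKDTree(pts2)
    pairs = tree.query_pairs(_CHAIN_TOL)
    parent = np.arange(len(pts2))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    labels = np.array([find(i) for i in range(len(pts2))])
    # drop zero-length segments, build node adjacency
    adj: dict[int, list[int]] = {}
    for s in range(len(segments)):
        a, b = labels[2 * s], labels[2 * s + 1]
        if a == b:
            continue
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    coord = {lab: pts2[lab] for lab in adj}
    for lab, nbrs in adj.items():
        if len(nbrs) % 2 != 0:
            raise TopologyError("open contour: endpoint with odd segment degree")
    total = 0.0
    visited_edges = set()
    for start in sorted(adj):
        for first in adj[start]:
            if (start, first) in visited_edges or (first, start) in visited_edges:
                continue
            loop = [start]
            prev, cur = start, first
            visited_edges.add((start, first))
            closed = False
            for _ in range(4 * len(segments)):
                loop.append(cur)
                if cur == start:
                    closed = True
                    break
                nxt = None
                for cand in adj[cur]:
                    if cand != prev and (cur, cand) not in visited_edges \
                            and (cand, cur) not in visited_edges:
                        nxt = cand
                        break
                if nxt is None:
                    # allow doubling back through the partner of a degree-2 node
                    others = [c for c in adj[cur] if (cur, c) not in visited_edges
                              and (c, cur) not in visited_edges]
                    if not others:
                        break
                    nxt = others[0]
                visited_edges.add((cur, nxt))
                prev, cur = cur, nxt
            if not closed:
                raise TopologyError("open contour after chaining")
            poly = np.array([coord[lab] for lab in loop])
            x, y = poly[:-1, 0], poly[:-1, 1]
            x2, y2 = poly[1:, 0], poly[1:, 1]
            total += abs(0.5 * np.sum(x * y2 - x2 * y))
    if total == 0.0:
        raise TopologyError("no closed contour found in section")
    return float(total)
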