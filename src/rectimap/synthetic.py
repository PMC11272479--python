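"""Synthetic limbs, rectified sockets and cohort tables with known truth.

Real residual-limb scans and socket mould files are restricted healthcare
data, so every geometric and statistical stage of this package is exercised
against a generator with known ground truth instead:

* :func:`generate_limb` — a tapered surface of revolution with a rounded
  distal cap, plus landmarks and the seven rectification region masks at
  anatomically plausible stations (anterior = +x, distal = +z).
* :func:`generate_socket` — the limb with an exact global volume reduction
  (radial scaling, so every cross-section shrinks by VR% exactly), local
  flat-topped bumps at the region masks (inward for carves, outward for
  builds), and optional rigid pose perturbation and vertex noise.
* :func:`generate_cohort_table` — rectification profiles with a chosen
  PTB/TSB mixture, Gaussian-copula rank-correlation structure and optional
  explicit conditional rules, plus demographics.

Ground-truth region sizes are defined on the same scale the extraction
pipeline measures: the total limb-to-socket deviation at the bump peak.
Bump amplitudes are therefore offset by the local VR background along the
limb normal, so that ``extract_profile(generate_socket(limb, p)) ~ p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import DesignCohort
from .errors import RectimapError
from .mesh import (
    REGION_DIRECTIONS,
    LandmarkSet,
    RegionMaskSet,
    RigidTransform,
    SurfaceMesh,
    apply_transform,
)
from .rectification import PROFILE_VARIABLES, RectificationProfile

__all__ = [
    "SyntheticLimbSpec",
    "GroundTruth",
    "CohortStructure",
    "generate_limb",
    "generate_socket",
    "generate_cohort_table",
    "anterior_subpatellar_mask",
    "PERCENTILE_TRIPLETS",
]

#: Published-style (10th, 50th, 90th) percentile triplets per variable,
#: mm (VR in %): the realistic scale the cohort generator defaults to.
PERCENTILE_TRIPLETS = {
    "PT": (4.1, 5.8, 7.4),
    "FH": (1.0, 2.1, 3.8),
    "MP": (1.9, 3.2, 4.7),
    "LP": (2.1, 3.6, 5.1),
    "TC": (1.4, 2.7, 4.4),
    "DE": (1.5, 5.8, 10.0),
    "LMC": (3.0, 5.5, 9.3),
    "VR": (1.5, 4.3, 9.9),
}

_Z90 = 1.2815515655446004  # standard normal 90th percentile


def _default_marginals() -> dict[str, tuple[float, float]]:
    return {
        var: (mid, (hi - lo) / (2 * _Z90))
        for var, (lo, mid, hi) in PERCENTILE_TRIPLETS.items()
    }


# angular sectors (deg, anterior = 0) and axial bands (fractions of length)
# for the seven region masks; LMC has medial and lateral lobes.
_REGION_LAYOUT = {
    "PT": ((-24, 24), (0.12, 0.24)),
    "FH": ((70, 110), (0.16, 0.30)),
    "MP": ((-58, -27), (0.26, 0.56)),
    "LP": ((27, 58), (0.26, 0.56)),
    "TC": ((-14, 14), (0.30, 0.58)),
    "LMC": (((60, 120), (-120, -60)), (0.04, 0.14)),
    # DE is the distal cap, handled separately
}


@dataclass
class SyntheticLimbSpec:
    """Parameters of the synthetic residual limb.

    Defaults describe a plausible adult transtibial residuum: 180 mm long,
    55 mm proximal radius tapering linearly to 35 mm, with a rounded distal
    cap.  ``taper`` may be any monotone radius function of the axial
    fraction in [0, 1] (of the barrel), overriding the linear default.
    """

    length: float = 180.0
    proximal_radius: float = 55.0
    distal_radius: float = 35.0
    taper: Callable[[np.ndarray], np.ndarray] | None = None
    cap_curvature: float = 0.8   # cap height as a fraction of distal radius
    n_theta: int = 180
    n_axial: int = 120
    seed: int = 0

    def __post_init__(self):
        if self.length <= 0 or self.proximal_radius <= 0 or self.distal_radius <= 0:
            raise RectimapError("limb dimensions must be positive")
        if self.n_theta < 90 or self.n_axial < 60:
            raise RectimapError(
                "resolution below minimum (90 angular x 60 axial) for "
                "recovery guarantees"
            )

    def radius_at(self, z_frac: np.ndarray) -> np.ndarray:
        """Barrel radius at axial fraction of the barrel length."""
        if self.taper is not None:
            return np.asarray(self.taper(z_frac), dtype=float)
        return self.proximal_radius + (self.distal_radius - self.proximal_radius) * z_frac


@dataclass
class GroundTruth:
    """What was actually applied to build a synthetic socket."""

    profile: RectificationProfile
    bump_centres: dict = field(default_factory=dict)   # region -> list of vertex ids
    bump_widths: dict = field(default_factory=dict)    # region -> (sigma_theta, sigma_z) or sigma_mm
    pose: RigidTransform | None = None
    noise_sd: float = 0.0
    seed: int | None = None
    #: sizes actually realised on the surface.  A carve whose requested
    #: total depth is below the local VR background cannot be built (the
    #: global shrink already exceeds it); its realised size is the
    #: background depth at the bump centre.
    realized_profile: RectificationProfile | None = None


def generate_limb(
    spec: SyntheticLimbSpec,
) -> tuple[SurfaceMesh, LandmarkSet, RegionMaskSet]:
    """Tapered limb-like surface of revolution with landmarks and masks.

    The limb axis is +z (distal), anterior is +x, lateral +y.  The mesh is
    open proximally (like a real scan) and closed by a rounded cap distally.
    Deterministic: the same spec always yields byte-identical arrays.
    """
    L = spec.length
    cap_h = spec.cap_curvature * spec.distal_radius
    Lb = L - cap_h
    if Lb <= 0:
        raise RectimapError("cap height exceeds limb length")
    n_cap = max(10, spec.n_axial // 6)
    z_barrel = np.linspace(0.0, Lb, spec.n_axial)
    # cap rings: ellipse from (r_d, Lb) to the apex (0, L); skip the apex ring
    phi = np.linspace(0.0, np.pi / 2, n_cap + 1)[:-1]
    z_cap = Lb + cap_h * np.sin(phi[1:])
    r_cap = spec.radius_at(np.ones(1))[0] * np.cos(phi[1:])
    z_all = np.concatenate([z_barrel, z_cap])
    r_all = np.concatenate([spec.radius_at(z_barrel / Lb), r_cap])
    theta = np.linspace(0.0, 2 * np.pi, spec.n_theta, endpoint=False)
    nt = spec.n_theta
    rings = len(z_all)
    vv = np.empty((rings * nt + 1, 3))
    for i, (zz, rr) in enumerate(zip(z_all, r_all)):
        vv[i * nt:(i + 1) * nt, 0] = rr * np.cos(theta)
        vv[i * nt:(i + 1) * nt, 1] = rr * np.sin(theta)
        vv[i * nt:(i + 1) * nt, 2] = zz
    apex = rings * nt
    vv[apex] = (0.0, 0.0, L)
    faces = []
    for i in range(rings - 1):
        a = i * nt + np.arange(nt)
        b = i * nt + (np.arange(nt) + 1) % nt
        c = a + nt
        d = b + nt
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    last = (rings - 1) * nt + np.arange(nt)
    nxt = (rings - 1) * nt + (np.arange(nt) + 1) % nt
    faces.append(np.column_stack([last, nxt, np.full(nt, apex)]))
    mesh = SurfaceMesh(vv, np.vstack(faces))

    def on_surface(theta_deg: float, z_frac: float) -> np.ndarray:
        zz = z_frac * L
        rr = spec.radius_at(np.array([min(zz, Lb) / Lb]))[0]
        th = np.deg2rad(theta_deg)
        return np.array([rr * np.cos(th), rr * np.sin(th), zz])

    landmarks = LandmarkSet({
        "mid_patella": on_surface(0.0, 0.10),
        "mid_patellar_tendon": on_surface(0.0, 0.18),
        "distal_tibia": on_surface(0.0, 0.80),
    })

    th_deg = np.rad2deg(np.arctan2(vv[:, 1], vv[:, 0]))
    zf = vv[:, 2] / L
    masks = {}
    for name, (sector, band) in _REGION_LAYOUT.items():
        lo, hi = band
        in_band = (zf >= lo) & (zf <= hi)
        sectors = sector if isinstance(sector[0], tuple) else (sector,)
        in_sector = np.zeros(len(vv), dtype=bool)
        for s0, s1 in sectors:
            in_sector |= (th_deg >= s0) & (th_deg <= s1)
        masks[name] = np.nonzero(in_band & in_sector)[0]
    masks["DE"] = np.nonzero(vv[:, 2] >= Lb)[0]  # distal cap incl. apex
    return mesh, landmarks, RegionMaskSet(masks)


def anterior_subpatellar_mask(
    limb: SurfaceMesh,
    landmarks: LandmarkSet,
    half_angle_deg: float = 45.0,
    distal_fraction: float = 0.40,
) -> np.ndarray:
    """Vertex mask of the anterior, sub-patellar band used to drive ICP.

    Angular sector of +/- ``half_angle_deg`` about anterior (+x), axially
    from the mid-patellar-tendon level down to ``distal_fraction`` of the
    limb length.
    """
    v = limb.vertices
    z0 = float(landmarks["mid_patellar_tendon"][2])
    z1 = distal_fraction * float(v[:, 2].max())
    th = np.abs(np.rad2deg(np.arctan2(v[:, 1], v[:, 0])))
    sel = (th <= half_angle_deg) & (v[:, 2] >= z0) & (v[:, 2] <= z1)
    return np.nonzero(sel)[0]


def _lobes_by_theta(theta_deg: np.ndarray, idx: np.ndarray) -> list[np.ndarray]:
    """Split a mask into lobes by the sign of the angular coordinate."""
    pos = idx[theta_deg[idx] >= 0]
    neg = idx[theta_deg[idx] < 0]
    return [lob for lob in (pos, neg) if lob.size]


def generate_socket(
    limb: SurfaceMesh,
    profile: RectificationProfile,
    masks: RegionMaskSet,
    pose: RigidTransform | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    width_fraction: float = 0.5,
) -> tuple[SurfaceMesh, GroundTruth]:
    """Socket mould realising a known rectification profile on a limb.

    Volume reduction is applied as an exact radial scaling by
    sqrt(1 - VR/100) about the +z axis, then each region receives a
    flat-topped bump (super-Gaussian, exp(-rho^4/2)) along the limb vertex
    normals — inward for carves, outward for builds — whose amplitude is
    offset by the local VR background so the *total* deviation at the bump
    peak equals the profile's size.  An optional rigid pose perturbation
    and i.i.d. vertex noise are appended last.

    ``width_fraction`` scales the bump widths relative to each region's
    half-extent; widths above the region extent are rejected.
    """
    if any(getattr(profile, v) < 0 for v in PROFILE_VARIABLES[:-1]):
        raise RectimapError("profile sizes must be non-negative")
    if not 0 < width_fraction <= 1.0:
        raise RectimapError("bump width exceeds region extent")
    v = limb.vertices
    normals = limb.vertex_normals
    theta = np.rad2deg(np.arctan2(v[:, 1], v[:, 0]))
    s = np.sqrt(1.0 - profile.VR / 100.0)
    scaled = v.copy()
    scaled[:, 0] *= s
    scaled[:, 1] *= s
    # carve-positive VR background along each limb normal
    background = np.einsum("ij,ij->i", v - scaled, normals)

    displacement = np.zeros(len(v))
    centres: dict[str, list[int]] = {}
    widths: dict[str, list] = {}
    realized: dict[str, float] = {}
    apex_i = int(np.argmax(v[:, 2]))
    for name, direction in REGION_DIRECTIONS.items():
        size = float(getattr(profile, name))
        realized[name] = size
        if size == 0.0:
            continue
        idx = masks[name]
        lobes = _lobes_by_theta(theta, idx) if name == "LMC" else [idx]
        centres[name] = []
        widths[name] = []
        for lobe in lobes:
            if name == "DE":
                centre_i = apex_i
                dmax = float(np.max(np.linalg.norm(v[lobe] - v[centre_i], axis=1)))
                sigma = width_fraction * dmax
                rho2 = (np.linalg.norm(v - v[centre_i], axis=1) / sigma) ** 2
            else:
                th_l = theta[lobe]
                # circular mean of the lobe's angles
                th_c = np.rad2deg(np.arctan2(
                    np.mean(np.sin(np.deg2rad(th_l))),
                    np.mean(np.cos(np.deg2rad(th_l))),
                ))
                z_c = 0.5 * (v[lobe, 2].min() + v[lobe, 2].max())
                half_th = 0.5 * np.ptp(
                    (th_l - th_c + 180.0) % 360.0 - 180.0
                )
                half_z = 0.5 * np.ptp(v[lobe, 2])
                s_th = width_fraction * max(half_th, 1e-6)
                s_z = width_fraction * max(half_z, 1e-6)
                dth = (theta - th_c + 180.0) % 360.0 - 180.0
                rho2 = (dth / s_th) ** 2 + ((v[:, 2] - z_c) / s_z) ** 2
                centre_i = int(lobe[np.argmin(rho2[lobe])])
                sigma = (s_th, s_z)
            shape = np.where(rho2 <= 16.0, np.exp(-0.5 * rho2 ** 2), 0.0)
            sign = 1.0 if direction == "carve" else -1.0
            amp = size - sign * background[centre_i]
            if amp < 0.0:  # carve shallower than the VR background
                amp = 0.0
                realized[name] = max(realized[name], background[centre_i])
            displacement += sign * amp * shape
            centres[name].append(centre_i)
            widths[name].append(sigma)
    socket_v = scaled - displacement[:, None] * normals
    socket = SurfaceMesh(socket_v, limb.faces.copy())
    rng = np.random.default_rng(seed)
    if pose is not None:
        socket = apply_transform(socket, pose)
    if noise_sd > 0:
        socket = SurfaceMesh(
            socket.vertices + rng.normal(0.0, noise_sd, socket.vertices.shape),
            socket.faces,
        )
    truth = GroundTruth(
        profile=profile, bump_centres=centres, bump_widths=widths,
        pose=pose, noise_sd=noise_sd, seed=seed,
        realized_profile=RectificationProfile(
            **realized, VR=profile.VR, socket_id=profile.socket_id,
            design_label=profile.design_label,
        ),
    )
    return socket, truth


# -- cohort tables -----------------------------------------------------------

# Table-1-like demographic marginals (per-socket counts)
_SEX_P = {"F": 51 / 162, "M": 111 / 162}
_DESIGN_P = {"PTB": 135 / 163, "TSB": 21 / 163, "PTB-SC": 7 / 163}
_REASON_COUNTS = {"dysvascularity": 63, "trauma": 47, "infection": 26,
                  "neuro": 10, "neoplasia": 6, "congenital": 3}
_KLEVEL_P = np.array([22, 61, 74, 6]) / 163
_SCS_P = np.array([3, 3, 21, 54, 48, 28]) / 157  # scores 5..10

#: Default rank-correlation targets between design variables (only pairs
#: with a stated target; all others default to 0).
DEFAULT_SPEARMAN_TARGETS = {
    ("MP", "LP"): 0.66,
    ("FH", "VR"): 0.38,
    ("TC", "MP"): -0.40,
    ("TC", "LP"): -0.35,
    ("TC", "FH"): 0.37,
    ("DE", "FH"): -0.32,
    ("LP", "FH"): -0.26,
    ("LP", "VR"): -0.25,
}


def _target_matrix(targets: dict) -> np.ndarray:
    k = len(PROFILE_VARIABLES)
    M = np.eye(k)
    pos = {v: i for i, v in enumerate(PROFILE_VARIABLES)}
    for (a, b), r in targets.items():
        M[pos[a], pos[b]] = M[pos[b], pos[a]] = r
    return M


@dataclass
class CohortStructure:
    """Statistical structure of a generated cohort.

    ``spearman_targets`` maps variable pairs to target rank correlations
    (Gaussian copula); ``design_offsets`` shifts marginal means per design
    label (the PTB/TSB contrast); ``conditional_rules`` optionally forces a
    target variable's category to follow an explicit conditional pmf given
    a conditioning variable's category, e.g. the distal-end-elongation
    choice following the volume-reduction choice.
    """

    tsb_weight: float | None = None          # None -> Table-1-like mixture
    marginals: dict = field(default_factory=_default_marginals)
    spearman_targets: dict = field(default_factory=lambda: dict(DEFAULT_SPEARMAN_TARGETS))
    design_offsets: dict = field(default_factory=lambda: {
        "TSB": {"LP": -1.5, "MP": -1.0, "DE": -3.0, "VR": 3.0},
    })
    conditional_rules: dict = field(default_factory=dict)
    # e.g. {("DE", "VR"): {"low": (0.44, 0.28, 0.28),
    #                      "mid": (1/3, 1/3, 1/3),
    #                      "high": (0.15, 0.35, 0.50)}}


def generate_cohort_table(
    n: int,
    structure: CohortStructure | None = None,
    seed: int = 0,
) -> DesignCohort:
    """Cohort of n rectification profiles with demographics.

    Design-variable values are drawn through a Gaussian copula matching the
    requested rank-correlation targets (Spearman rho converted to Pearson
    via 2 sin(pi rho / 6)), with per-design mean offsets and truncation at
    0.05 (sizes are physical magnitudes).  Explicit conditional rules, when
    given, resample the target variable's value from its marginal truncated
    to the category drawn from the rule's pmf.  Deterministic per seed.
    """
    structure = structure or CohortStructure()
    rng = np.random.default_rng(seed)
    k = len(PROFILE_VARIABLES)
    S = _target_matrix(structure.spearman_targets)
    P = 2.0 * np.sin(np.pi * S / 6.0)
    np.fill_diagonal(P, 1.0)
    evals = np.linalg.eigvalsh(P)
    if evals.min() <= 1e-10:
        raise RectimapError("correlation target is not positive definite")
    z = rng.multivariate_normal(np.zeros(k), P, size=n, method="cholesky")

    if structure.tsb_weight is None:
        design = rng.choice(list(_DESIGN_P), size=n, p=list(_DESIGN_P.values()))
    else:
        w = structure.tsb_weight
        design = rng.choice(["PTB", "TSB"], size=n, p=[1 - w, w])

    from scipy.stats import norm

    cols = {}
    for j, var in enumerate(PROFILE_VARIABLES):
        mean, sd = structure.marginals[var]
        x = mean + sd * z[:, j]
        for label, offs in structure.design_offsets.items():
            if var in offs:
                x = x + np.where(design == label, offs[var], 0.0)
        cols[var] = np.maximum(x, 0.05)

    # Conditional rules are imposed self-consistently with the analysis:
    # categories come from the same KDE-percentile cuts the modelling stage
    # will fit, computed on the realised sample (second pass).
    from .design_model import categorize, fit_size_categories

    for (target, cond), rule in structure.conditional_rules.items():
        mean_t, sd_t = structure.marginals[target]
        cond_cuts = fit_size_categories(cols[cond], cond)
        target_cuts = fit_size_categories(cols[target], target)
        cond_cat = categorize(cols[cond], cond_cuts)
        bounds = {"low": (-np.inf, target_cuts.cut_low),
                  "mid": (target_cuts.cut_low, target_cuts.cut_high),
                  "high": (target_cuts.cut_high, np.inf)}
        new_vals = np.empty(n)
        for i in range(n):
            pmf = np.asarray(rule[cond_cat[i]], dtype=float)
            cat = rng.choice(("low", "mid", "high"), p=pmf / pmf.sum())
            a, b = bounds[cat]
            fa = norm.cdf(a, loc=mean_t, scale=sd_t)
            fb = norm.cdf(b, loc=mean_t, scale=sd_t)
            new_vals[i] = norm.ppf(rng.uniform(fa, fb), loc=mean_t, scale=sd_t)
        cols[target] = np.maximum(new_vals, 0.05)

    reasons = list(_REASON_COUNTS)
    rp = np.array(list(_REASON_COUNTS.values()), dtype=float)
    table = pd.DataFrame({
        "socket_id": [f"S{seed:04d}-{i:04d}" for i in range(n)],
        "design": design,
        "PT_mm": cols["PT"], "FH_mm": cols["FH"], "MP_mm": cols["MP"],
        "LP_mm": cols["LP"], "TC_mm": cols["TC"], "DE_mm": cols["DE"],
        "LMC_mm": cols["LMC"], "VR_pct": cols["VR"],
        "sex": rng.choice(list(_SEX_P), size=n, p=list(_SEX_P.values())),
        "age": np.round(np.clip(rng.normal(57.7, 15.4, n), 19, 95), 1),
        "reason": rng.choice(reasons, size=n, p=rp / rp.sum()),
        "time_since_amputation": np.round(
            np.clip(rng.lognormal(np.log(1.2), 1.3, n), 0.1, 70.3), 2),
        "k_level": rng.choice([1, 2, 3, 4], size=n, p=_KLEVEL_P),
        "scs": rng.choice([5, 6, 7, 8, 9, 10], size=n, p=_SCS_P),
    })
    return DesignCohort(table)
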