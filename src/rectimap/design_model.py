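"""KDE size categories, Gaussian Naive Bayes design association, templates.

Rectification sizes across a cohort are summarised by a Gaussian kernel
density estimate; the fitted density is split at its 33rd and 67th
percentiles into low / mid / high categories, and reduced further to
exemplar single values at the 10th, 50th and 90th percentiles.

A Gaussian Naive Bayes model then estimates the probability that a
prosthetist chooses a low / mid / high size of one rectification (the
*target*) given the already-chosen continuous size of another (the
*conditioning* variable): class priors are empirical category frequencies
of the target, and the conditioning value's likelihood within each class is
Gaussian.  Chaining the most probable categories across all variables from
one initial choice produces a most-probable "template" design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ModelError, RegionError
from .mesh import (
    REGION_DIRECTIONS,
    LandmarkSet,
    RegionMaskSet,
    SurfaceMesh,
    principal_axis,
)
from .rectification import PROFILE_VARIABLES, DeviationMap
from .cohort import DesignCohort

__all__ = [
    "SizeCategories",
    "ConditionalDesignModel",
    "fit_kde",
    "kde_percentiles",
    "fit_size_categories",
    "fit_all_categories",
    "categorize",
    "fit_conditional_nb",
    "conditional_probabilities",
    "generate_template",
    "render_template_map",
    "apply_deviation_map",
]

CATEGORIES = ("low", "mid", "high")

_VAR2COL = dict(zip(PROFILE_VARIABLES,
                    ("PT_mm", "FH_mm", "MP_mm", "LP_mm", "TC_mm", "DE_mm",
                     "LMC_mm", "VR_pct")))


@dataclass
class SizeCategories:
    """Category cut points and exemplar sizes for one design variable.

    ``cut_low``/``cut_high`` are the 33rd/67th percentiles of the fitted
    KDE; exemplars are its 10th/50th/90th percentiles.  All in the
    variable's own unit (mm, or % for VR).
    """

    variable: str
    cut_low: float
    cut_high: float
    exemplar_low: float
    exemplar_mid: float
    exemplar_high: float

    def __post_init__(self):
        if not (self.cut_low <= self.cut_high):
            raise ModelError("cut_low must not exceed cut_high")
        if not (self.exemplar_low <= self.exemplar_mid <= self.exemplar_high):
            raise ModelError("exemplars must be non-decreasing")

    def exemplar(self, category: str) -> float:
        return {"low": self.exemplar_low, "mid": self.exemplar_mid,
                "high": self.exemplar_high}[category]


@dataclass
class ConditionalDesignModel:
    """Gaussian NB model P(target category | conditioning value)."""

    target: str
    conditioning: str
    priors: np.ndarray           # (3,) class priors, sum to 1
    means: np.ndarray            # (3,) conditioning mean per target class
    variances: np.ndarray        # (3,) conditioning variance per class
    var_floor: float
    class_counts: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.priors = np.asarray(self.priors, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ModelError("class priors must sum to 1")
        if np.any(self.variances < self.var_floor) or self.var_floor <= 0:
            raise ModelError("class variances must be >= var_floor > 0")


def fit_kde(values, bandwidth_rule: str = "scott") -> sps.gaussian_kde:
    """Gaussian-kernel density of a 1-D sample.

    Bandwidth follows Scott's rule, h = n^(-1/5) * sample s.d. (the scipy
    Scott factor for one dimension).  Requires at least 5 values with
    non-zero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ModelError("need at least 5 values to fit a KDE")
    if np.std(x, ddof=1) == 0:
        raise ModelError("zero-variance sample: KDE degenerate")
    return sps.gaussian_kde(x, bw_method=bandwidth_rule)


def _kde_grid(kde: sps.gaussian_kde, grid_size: int = 512):
    x = kde.dataset.ravel()
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, grid_size)
    pdf = kde(grid)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    return grid, pdf, cdf


def kde_percentiles(kde: sps.gaussian_kde, probs, grid_size: int = 512) -> np.ndarray:
    """Invert the fitted KDE's CDF at the given probabilities.

    The density is integrated (trapezoid) on a 512-point grid spanning
    [min - 4h, max + 4h] and inverted by monotone linear interpolation; the
    CDF is normalised by its endpoint (which is 1 within ~1e-3 by
    construction) so the inversion is exact at the grid resolution.
    """
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if np.any((probs <= 0) | (probs >= 1)):
        raise ModelError("probs must lie strictly inside (0, 1)")
    grid, _, cdf = _kde_grid(kde, grid_size)
    cdf = cdf / cdf[-1]
    return np.interp(probs, cdf, grid)


def fit_size_categories(values, variable: str = "?") -> SizeCategories:
    """Fit the KDE and extract cut points and exemplars for one variable."""
    kde = fit_kde(values)
    q = kde_percentiles(kde, [0.10, 0.33, 0.50, 0.67, 0.90])
    return SizeCategories(variable=variable, cut_low=float(q[1]),
                          cut_high=float(q[3]), exemplar_low=float(q[0]),
                          exemplar_mid=float(q[2]), exemplar_high=float(q[4]))


def fit_all_categories(cohort: DesignCohort) -> dict[str, SizeCategories]:
    """Size categories for all eight design variables of a cohort."""
    return {
        var: fit_size_categories(
            cohort.table[_VAR2COL[var]].dropna().to_numpy(), variable=var
        )
        for var in PROFILE_VARIABLES
    }


def categorize(value, cuts: SizeCategories):
    """Assign low / mid / high by the half-open rule.

    low if value < cut_low; mid if cut_low <= value < cut_high; high
    otherwise (values exactly at a cut fall in the upper category).
    """
    v = np.asarray(value, dtype=float)
    out = np.where(v < cuts.cut_low, "low",
                   np.where(v < cuts.cut_high, "mid", "high"))
    return out.item() if np.isscalar(value) or v.ndim == 0 else out


def fit_conditional_nb(
    cohort: DesignCohort,
    target: str,
    conditioning: str,
    cuts: dict[str, SizeCategories],
    min_class_size: int = 5,
) -> ConditionalDesignModel:
    """Fit the pairwise Gaussian NB model for one (target, conditioning) pair.

    Target classes come from :func:`categorize` on the target variable;
    priors are empirical class frequencies; per-class Gaussians are the
    within-class mean and variance of the conditioning variable.  Classes
    with fewer than ``min_class_size`` sockets borrow the pooled variance
    (with a warning); an empty class is an error (use coarser cuts).
    Variances are floored at 1e-9 times the overall variance.
    """
    tcol = cohort.table[_VAR2COL[target]].to_numpy(dtype=float)
    ccol = cohort.table[_VAR2COL[conditioning]].to_numpy(dtype=float)
    cats = categorize(tcol, cuts[target])
    overall_var = float(np.var(ccol, ddof=1))
    floor = max(1e-9 * overall_var, 1e-300)
    pooled = max(overall_var, floor)
    priors, means, variances, counts = [], [], [], []
    for c in CATEGORIES:
        sel = cats == c
        ncl = int(sel.sum())
        counts.append(ncl)
        if ncl == 0:
            raise ModelError(
                f"target class {c!r} of {target} is empty; use coarser cuts"
            )
        priors.append(ncl / len(tcol))
        means.append(float(np.mean(ccol[sel])))
        if ncl < min_class_size:
            warnings.warn(
                f"class {c!r} of {target} has only {ncl} sockets; "
                "using pooled variance", stacklevel=2,
            )
            variances.append(pooled)
        else:
            variances.append(max(float(np.var(ccol[sel], ddof=1)), floor))
    return ConditionalDesignModel(
        target=target, conditioning=conditioning,
        priors=np.array(priors), means=np.array(means),
        variances=np.array(variances), var_floor=floor,
        class_counts=np.array(counts),
    )


def conditional_probabilities(model: ConditionalDesignModel, x: float) -> np.ndarray:
    """(P_low, P_mid, P_high) at conditioning value ``x``, normalised to 1."""
    log_lik = (
        -0.5 * np.log(2 * np.pi * model.variances)
        - 0.5 * (x - model.means) ** 2 / model.variances
        + np.log(model.priors)
    )
    log_lik -= log_lik.max()
    p = np.exp(log_lik)
    return p / p.sum()


def generate_template(
    cohort: DesignCohort,
    cuts: dict[str, SizeCategories],
    chosen_variable: str,
    chosen_category: str,
) -> dict[str, tuple[str, float]]:
    """Most-probable design template following one initial choice.

    The chosen variable is fixed at its chosen category's exemplar value
    x*; every other variable gets the category maximising
    P(category | chosen_variable = x*) under its pairwise NB model, with
    ties broken toward the lower (more conservative) category, and is
    reported with that category's exemplar size.
    """
    if chosen_category not in CATEGORIES:
        raise ModelError(f"unknown category {chosen_category!r}")
    x_star = cuts[chosen_variable].exemplar(chosen_category)
    template: dict[str, tuple[str, float]] = {
        chosen_variable: (chosen_category, x_star)
    }
    for var in PROFILE_VARIABLES:
        if var == chosen_variable:
            continue
        model = fit_conditional_nb(cohort, target=var,
                                   conditioning=chosen_variable, cuts=cuts)
        p = conditional_probabilities(model, x_star)
        best = int(np.argmax(p))  # argmax returns the first (= lower) on ties
        cat = CATEGORIES[best]
        template[var] = (cat, cuts[var].exemplar(cat))
    return template


# -- rendering ---------------------------------------------------------------

def _vr_background(limb: SurfaceMesh, vr_pct: float) -> np.ndarray:
    """Carve-positive deviation field of a pure radial volume reduction.

    Shrinking every cross-section's area by VR% corresponds to scaling local
    radii by sqrt(1 - VR/100) about the limb's principal axis; the deviation
    seen along each vertex normal is the radial offset projected onto it.
    """
    axis, centroid = principal_axis(limb)
    s = np.sqrt(1.0 - vr_pct / 100.0)
    rel = limb.vertices - centroid
    axial = rel @ axis
    radial = rel - axial[:, None] * axis[None, :]
    offset = (1.0 - s) * radial  # vertex displacement inward
    return np.einsum("ij,ij->i", offset, limb.vertex_normals)


def render_template_map(
    template: dict[str, tuple[str, float]],
    limb: SurfaceMesh,
    masks: RegionMaskSet,
    landmarks: LandmarkSet,
) -> DeviationMap:
    """Render a template as a smooth per-vertex deviation field on a limb.

    Each region contributes a smooth flat-topped bump whose *total* deviation at
    the bump centre equals the template's exemplar size (carve positive,
    build negative, matching the rectification-map sign convention); the
    global VR choice contributes a uniform radial carve of
    (1 - sqrt(1 - VR/100)) x local radius.  Bump amplitudes are therefore
    offset by the local VR background so that rendered sizes read back as
    the template sizes.
    """
    n = len(limb.vertices)
    vr = template.get("VR", ("low", 0.0))[1]
    field_vals = _vr_background(limb, vr) if vr != 0 else np.zeros(n)
    for var, (_cat, size) in template.items():
        if var == "VR" or size == 0:
            continue
        if var not in masks:
            raise RegionError(f"region {var!r} missing from mask set")
        idx = masks[var]
        if idx.size == 0:
            raise RegionError(f"region {var!r} mask is empty")
        direction = REGION_DIRECTIONS[var]
        sign = 1.0 if direction == "carve" else -1.0
        # one bump per connected lobe of the mask (LMC has two lobes)
        for lobe in _mask_lobes(limb, idx):
            pts = limb.vertices[lobe]
            centre_i = lobe[int(np.argmin(
                np.linalg.norm(pts - pts.mean(axis=0), axis=1)))]
            centre = limb.vertices[centre_i]
            radius = float(np.max(np.linalg.norm(pts - centre, axis=1)))
            d = np.linalg.norm(limb.vertices - centre, axis=1)
            # flat-topped smooth bump (same profile the socket generator
            # uses): the plateau makes the 98th-percentile size estimator
            # read the peak back without downward bias at mesh resolution
            rho = d / max(0.5 * radius, 1e-9)
            shape = np.where(d < 2 * radius, np.exp(-0.5 * rho ** 4), 0.0)
            background_at_centre = field_vals[centre_i]
            amp = size - sign * background_at_centre
            field_vals = field_vals + sign * amp * shape
    return DeviationMap(values=field_vals, missing=np.zeros(n, dtype=bool))


def _mask_lobes(limb: SurfaceMesh, idx: np.ndarray) -> list[np.ndarray]:
    """Split a region mask into spatially connected lobes.

    Uses single-linkage over vertex positions with a threshold of 4x the
    median nearest-neighbour spacing — enough to separate the medial and
    lateral supracondylar lobes while keeping ordinary regions whole.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial import cKDTree

    pts = limb.vertices[idx]
    if len(pts) < 3:
        return [idx]
    d, _ = cKDTree(pts).query(pts, k=2)
    thresh = 4.0 * float(np.median(d[:, 1]))
    if len(pts) > 2000:  # subsampling not needed at package scales
        return [idx]
    labels = fcluster(linkage(pts, method="single"), t=thresh, criterion="distance")
    return [idx[labels == lab] for lab in np.unique(labels)]


def apply_deviation_map(limb: SurfaceMesh, dev_map: DeviationMap) -> SurfaceMesh:
    """Displace a limb mesh by a deviation field to realise a socket surface.

    Carve-positive deviations move vertices inward along their normals
    (the socket presses into the limb), builds move outward.
    """
    vals = np.where(dev_map.missing, 0.0, dev_map.values)
    return SurfaceMesh(limb.vertices - vals[:, None] * limb.vertex_normals,
                       limb.faces.copy())
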