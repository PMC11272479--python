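# Methods

This note records the models and conventions `rectimap` implements, the
choices made where the procedure was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Geometric pipeline

**Units and frames.** All lengths are millimetres, areas mm², volume
reduction percent. The canonical anatomical frame points the distal
direction along +z and anterior along +x. Meshes may be open (limb scans
are open proximally); watertightness is never required — only the contours
cut by sectioning planes must close.

**Principal axis.** The limb axis is the covariance eigenvector of the
vertex cloud with the largest eigenvalue. A near-isotropic cloud (largest
two eigenvalues within 1%) has no usable axis and raises an error. The sign
is fixed toward the vertex farthest from the centroid *along the axis*.
(A plain farthest-vertex rule is unstable for limb-like shapes: the wide
proximal rim can out-distance the distal tip by Euclidean distance and flip
the axis, which would scramble the coarse alignment below.)

**Alignment.** Socket moulds are registered to limb scans in two stages,
with an optional override transform standing in for the expert
inspect-and-adjust step used clinically:

1. *Coarse*: one Kabsch least-squares fit over four correspondences — the
   two centroids, one point offset along each principal axis (which aligns
   the axes), and the mid-patella and distal-tibia landmark pairs. The
   residual RMS over those correspondences is reported.
2. *ICP*: point-to-surface iterative closest point restricted to the
   anterior, sub-patellar vertex band (±45° about anterior, from the
   mid-patellar-tendon level to 40% of limb length — the extent of this
   band is a package convention; nothing canonical defines it). Each
   iteration matches masked limb vertices to their nearest point on the
   socket *surface* (point-to-triangle, chosen over vertex-to-vertex for
   mesh-resolution independence), solves Kabsch and applies the step.
   Iteration stops when RMS improvement drops below 1e-4 mm or at 50
   iterations; non-convergence sets a flag rather than raising. There is no
   outlier trimming by default; an optional maximum pair distance can
   discard far matches on rectified or noisy pairs.

Nearest-point and ray queries use vectorised exact primitives over
KD-tree candidate shortlists (48 nearest triangle centroids for closest
point, 128 for ray casting — the larger shortlist keeps steep rectification
flanks from shadowing the true intersection). Ties in the nearest triangle
break toward the lowest triangle index; the pipeline contains no
randomness.

*Identifiability caveat*: on an exact surface of revolution — which the
synthetic limb is — rotation about the limb axis is an isometry, so pure
surface-matching ICP cannot observe azimuth; landmarks in the coarse stage
pin it. On rectified pairs the anterior band contains carves, which biases
an unconstrained ICP by up to several tenths of a millimetre in the
deviation map; the coarse stage, driven by landmarks, is unbiased, and the
override slot exists for cases an expert would refine.

**Rectification map.** For every limb vertex a ray is cast along its
outward normal (area-weighted average of face normals) in both directions;
the nearest socket intersection within 50 mm gives the signed deviation,
positive when the socket lies inward of the limb (carve), negative outward
(build). Vertices with no intersection are *missing* and excluded from
region statistics; a region errors when more than half its mask is missing,
and a fully disjoint pair errors immediately.

**Region sizes.** Each of the seven regions (PT, FH, MP, LP, TC, DE, LMC)
is a manually defined vertex cluster with a fixed expected direction.
Deviations over the cluster are oriented so the expected direction is
positive and summarised by the 98th percentile (linear interpolation
between order statistics) — not the maximum, to suppress single-vertex
noise. The percentile is taken over *signed* oriented deviations (whether
it should instead be over absolute deviations is ambiguous; the signed
reading is adopted). Sizes are floored at zero when the field opposes the
expected direction; the raw signed percentile is kept in diagnostics.
At least 10 measurable vertices are required per region.

**Volume reduction.** Ten planes perpendicular to the limb principal axis,
spaced equally with *inclusive* endpoints between the axial levels of the
mid-patellar-tendon and distal-tibia landmarks (inclusive vs exclusive is
not canonically defined; inclusive is the package convention). Per plane,
triangle-plane intersection segments are chained into closed contours
(endpoints matched within 1e-6 mm) and summed by the shoelace formula;
VR = mean over sections of (A_limb − A_socket)/A_limb × 100. The
per-section *relative* mean is used rather than a single total-volume ratio
or a mean absolute area difference, because VR is a percentage. VR may be
negative only when the socket is globally larger than the limb; profiles
flag this case.

## Statistical analysis

**Cohort container.** One row per socket: the eight design variables plus
sex, age, reason for amputation (may be missing for individual sockets),
time since amputation, design label (PTB / TSB / PTB-SC), K-level 1–4 and
optional socket comfort score 1–10. One person can contribute several
sockets; all statistics are per socket, and no per-individual collapsing is
attempted.

**Summaries** report, per stratum: n, sex and design counts, design shares
within the stratum, mean (s.d.) age, median (range) time since amputation
(amputation times are heavily right-skewed), K-level counts with the
count-weighted mean, SCS counts and mean, and the stratum's share of the
cohort. Means print to one decimal, shares to the nearest percent.

**Rank statistics.** Rectification sizes are not normally distributed, so
group comparisons use the Mann–Whitney U test: exact enumeration over rank
assignments when n_A + n_B ≤ 16 with no ties, otherwise the tie-corrected
normal approximation with continuity correction (via scipy). PTB-SC sockets
pool with PTB by default for the two-group comparison (configurable).
Bonferroni correction uses m = 8 by default — one test per design variable;
m is configurable since the appropriate family size is a judgement call.
Pairwise association uses Spearman's ρ (Pearson correlation of midranks,
two-sided p from the t approximation with n − 2 df). A constant variable
yields missing correlations, never zero. Positive ρ means two
rectifications grow together on their own carve/build scales.

**KDE categories.** Per variable, a Gaussian-kernel density with Scott's
bandwidth h = n^(−1/5)·s.d. (the rule is configurable; nothing canonical
fixes it) is integrated on a 512-point grid over [min − 4h, max + 4h] and
inverted to percentiles. Categories split at the *fitted density's* 33rd
and 67th percentiles (an empirical-quantile option exists behind the same
interface); exemplars sit at the 10th/50th/90th percentiles.
Categorisation is half-open: values exactly at a cut fall upward.

**Gaussian Naïve Bayes.** For a (target, conditioning) pair, target classes
come from categorising the target variable; priors are empirical class
frequencies (not uniform — the empirical choice reflects how often each
size class is actually used); the conditioning variable gets a Gaussian
per class, with unbiased (ddof = 1) variances floored at 1e-9 × the overall
variance. Classes under 5 sockets borrow the pooled variance with a
warning; an empty class is an error. Conditioning is on the *raw
continuous* value, consistent with a Gaussian likelihood — one conditioning
feature per model, matching pairwise usage; multi-feature conditioning is
possible through repeated calls but not a default. Posteriors are computed
in log space and normalised.

**Templates.** Fixing one variable at a chosen category's exemplar x*, every
other variable receives the category maximising P(category | x*) under its
pairwise NB model — ties break toward the lower (more conservative)
category — and is reported with that category's exemplar. Rendering a
template paints each region with a smooth flat-topped bump (super-Gaussian,
exp(−ρ⁴/2), falling to ~0 at the mask boundary; the LMC mask renders one
bump per connected lobe) plus a uniform radial carve of
(1 − √(1 − VR/100)) × local radius for the VR choice. Bump amplitudes are
offset by the local VR background so the *total* deviation at each peak
equals the exemplar size — the rendered map reads back through
`extract_profile` to within 10%. A sharply peaked profile (e.g. a cosine
cap) would be read 10–17% low by the 98th-percentile estimator at ordinary
mesh resolutions, which is why the flat top is used. Templates render onto
any supplied limb mesh.

## Synthetic data: what it emulates

`generate_limb` builds a tapered surface of revolution (default: 180 mm
long, 55 mm proximal radius tapering linearly to 35 mm, rounded distal cap
at 0.8 × distal radius; 180 angular × 120 axial vertices) with landmarks at
fixed parametric stations and the seven region masks as angular-sector ×
axial-band vertex sets at anatomically plausible positions. The defaults
describe a plausible adult transtibial residuum; they are package
conventions, not measured values. A minimum resolution of 90 × 60 is
enforced — below it the 98th-percentile size estimator loses its accuracy
guarantees.

`generate_socket` applies, in order: (1) volume reduction as an exact
radial scaling by √(1 − VR/100) about the limb axis, so every
cross-section's area shrinks by exactly VR%; (2) per-region flat-topped
bumps along the limb vertex normals, inward for carves and outward for
builds, with widths at half the region half-extent; (3) optional rigid
pose perturbation and i.i.d. vertex noise. Ground-truth sizes are defined
as the **total limb-to-socket deviation at the bump peak** — the same
scale the extractor measures — so bump amplitudes are offset by the local
VR background along the normal. A carve whose requested total depth is
below the local VR background cannot be built (the global shrink already
exceeds it); the generator clamps the bump away and records the realised
depth in `GroundTruth.realized_profile`, which is the reference for
inverse-recovery checks.

`generate_cohort_table` draws the eight variables through a Gaussian copula
(target Spearman ρ converted to Pearson via 2·sin(πρ/6); a
non-positive-definite target errors). Default marginals are normal with
means at mid-size exemplar scale and s.d. = (high − low)/(2 × 1.2816),
truncated at 0.05 mm; default rank-correlation targets reproduce the
strongest published pairwise associations (MP–LP 0.66, FH–VR 0.38, TC–MP
−0.40, …). The PTB/TSB contrast enters as mean offsets for TSB sockets
(smaller paratibial carves and distal elongation, larger VR). Explicit
conditional rules (e.g. the distal-end category following the
volume-reduction category with pmf rows 44/28/28, uniform, 15/35/50)
resample the target variable from its marginal truncated to the drawn
category's interval; the rule's categories use the same KDE-percentile cuts
the analysis fits, so imposition and measurement are self-consistent.
Demographics are drawn from fixed reference marginals (sex ratio, age,
cause-of-amputation and K-level/SCS distributions of a published UK
service-evaluation population).

**What passing synthetic tests does not show.** The generator's surfaces
are smooth, axially symmetric and noise-free by default: real scans have
asymmetric geometry, soft-tissue artefacts, scanner noise and imperfect
landmarks, all of which degrade alignment and sizing accuracy beyond what
the recovery suites measure. The cohort generator's normal marginals and
single global copula are a deliberate simplification of real design
practice. Pipeline correctness — sign conventions, estimator bias,
statistical machinery — is what the synthetic suite establishes.

## Numerical choices

* Duplicate-vertex merge at 1e-9 mm (below scanner resolution, above float
  noise); contour chaining at 1e-6 mm; zero-area faces dropped at
  construction.
* Rotations validated orthonormal with det +1 within 1e-9; landmark and
  coordinate values must be finite.
* Deviation-map search cutoff 50 mm; NB variance floor 1e-9 × overall
  variance; KDE CDF grid 512 points.
* The Gaussian-NB readout of an imposed piecewise-constant conditional rule
  is structurally attenuated (Gaussian class-conditionals smooth the
  sharp rule): a generating P(high | high) of 0.50 reads back around
  0.43–0.47 at n = 163. The recovery checks compare seed-averaged readouts
  and account for this smoothing as part of the method under test.

## Known limitations

* Region masks are inputs (as in manual clinical delineation); the package
  does not segment rectification zones automatically, and describes
  rectifications by size only — not area, shape or location.
* Non-rigid registration and scaling are out of scope; sockets are assumed
  rigid-comparable to their limbs.
* The deposited-cohort checks require an external download; they validate
  the statistics reproduce published values but are not runnable offline.
* Statistics are per socket; repeated sockets from one individual are not
  modelled as clustered observations.
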