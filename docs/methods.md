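# Methods

`morphfit` implements the geometric and statistical machinery of
single-image 3D face-shape reconstruction for clinical use (e.g. facial
palsy assessment, where preserving individual asymmetry matters): a PCA
morphable model of corresponded face meshes, landmark-based fitting
under a scaled orthographic camera, the analytic model and loss
components of two deep-reconstruction pipelines, and surface-distance
validation against reference meshes. Network training, rendering,
landmark detection and medical-image segmentation are outside its
scope; their outputs (landmark coordinates, deep-feature vectors,
pixel arrays, reference meshes) enter as data.

## Shape model

A corpus of n corresponded meshes (identical vertex count and face
list) is flattened per vertex, `(x1, y1, z1, ..., xm, ym, zm)`, into an
n x 3m matrix. The model is

S(α) = S0 + Σ_j B_j · sd_j · α_j,

with S0 the mean, B the top-k left singular vectors of the centered
data matrix (thin SVD; the 3m x 3m covariance is never formed), and
sd_j = σ_j / √(n−1). At most n−1 modes exist. Coefficients α are
dimensionless, in units of sd — under the implicit Gaussian population
model, α ~ N(0, I), so a Mahalanobis prior is the isotropic ridge
‖α‖². Basis sign is fixed (largest-magnitude entry positive) for
bit-stable builds. The default k is the smallest explaining ≥ 99% of
variance, overridable.

A corpus with (numerically) zero variance yields zero mode SDs; this
is flagged with `ZeroVarianceWarning` rather than raised, since the
mean and the requested mode count are still well defined.

Units are millimetres throughout; mesh readers take coordinates as-is
(a `scale` argument converts metre-authored files). STL input is
accepted only for validation meshes: the format stores one vertex
triplet per facet and destroys the shared indexing a corpus needs.

## Camera and landmark fitting

The camera is weak perspective (scaled orthographic): for a face ~1 m
from the camera the depth extent is small relative to distance, so

SOP(p) = s · (R p)[0:2] + s · t,

with R a rotation, s in pixels/mm, and t the 2D translation in model
units (s·t is the pixel offset). Image coordinates are raster:
origin top-left, x right, y down, pixel centres at integers.

**Pose from known 3D points** is POS — solve the 2x3 affine camera by
linear least squares, project to the nearest scaled rotation via SVD
(s = mean of the two singular values, third row by cross product) —
followed by a Gauss-Newton refinement ("POS with iteration") on
(rotation increment, t, s) that reaches the nonlinear least-squares
optimum; each GN step is accepted only if the residual decreases.
Fewer than 4 correspondences or collinear 3D points are rejected;
coplanar sets warn.

**Shape from known pose** minimizes

E(α) = (1/L) Σ_i ‖x_i − SOP(f0_i + Σ_j B_ij sd_j α_j)‖² + λ‖α‖²,

a linear ridge system solved in closed form. λ = 0 is allowed when the
design is full rank and errors otherwise, advising λ > 0.

**The full fitter** alternates the two half-steps from α = 0 and the
mean-shape POS pose. Pure alternation contracts only linearly along
the weakly coupled pose/shape directions (observed contraction ~0.99
per sweep), so each outer iteration also applies a joint Gauss-Newton
step over (rotation, t, s, α) on the same objective with backtracking;
every step is accepted only if the cost decreases, so the recorded
cost trace is non-increasing by construction. On noiseless synthetic
data the fit converges in 3–4 outer iterations and, at λ = 0 with
L = 68 landmarks and k = 10 modes, recovers coefficients to machine
precision. With λ > 0 the optimum is biased: at λ = 1e−6 under the
synthetic conditions below the bias is ~1e−2 SD units in the weakest
modes (~5 µm of surface), at the default λ = 1e−3 proportionally more.
Defaults: λ = 1e−3 (noisy detections), rel_tol = 1e−8 on the cost,
max_iters = 100.

## Articulated model, dual 3DMM, and losses

The articulated head model is template + identity blendshapes + pose
correctives + expression blendshapes, then linear blend skinning over
k = 4 joints (neck, jaw, two eyeballs) with convex per-vertex weights;
the global rotation acts as the root of the joint hierarchy. The pose
corrective feature is the flattened per-joint (R − I), the standard
linearized construction. At θ = 0 skinning is skipped outright so the
rest pose returns the template bit-exactly.

The dual 3DMM is linear in identity/expression shape coefficients and
texture coefficients. Shading uses real spherical harmonics, bands
0–2 — exactly 9 basis functions per color channel — with one constant
table (`SH_CONSTANTS`) shared between the implementation and its test
oracle.

Losses (all ≥ 0, each vanishing on its exact-match input):

- photometric: attention-weighted mean of the **un-squared** per-pixel
  l2 color difference over the masked face region (many
  implementations square it; here un-squared is the definition);
- landmark: (1/N) Σ ω_n ‖q_n − q'_n‖ with default ω = 20 on mouth and
  nose slots and 0 elsewhere (kept as printed in the source method
  despite being an unusual choice; overridable);
- perception: 1 − cosine similarity of supplied deep features;
- coefficient regularizer: weights (1.0, 0.8, 0.0017) on squared norms
  of identity/expression/texture coefficient blocks;
- texture flattening: summed per-channel variance over a skin region;
- eye closure: Σ over eyelid pairs of |Δy_pred − Δy_detected|;
  shape-consistency: ‖β_a − β_b‖²; soft symmetry: mean |D − hflip(D)|;
  detail regularizer: ‖D‖².

The coarse and detail aggregates are unweighted sums of their named
components (per-term weights configurable); the MRF detail term is
defined externally and enters as a supplied scalar, default 0. A
missing component raises an error naming it.

## Validation

Error statistics are point-to-surface: each sample point is measured
to the exact nearest point of any reference triangle (vertex, edge,
interior cases all handled by a vectorized region-based closest-point
construction). Sample points are the source mesh's vertices, for
determinism. The headline is mean ± SD of these distances (SD is the
population SD of the per-point values); `max` is the classical
directed Hausdorff value. Symmetric mode pools both directions. The
source method's literature does not state whether its figures are
one-sided or symmetric, point-to-point or point-to-surface; these
defaults are this package's documented choices.

Registration is a trimmed similarity ICP: centroid + RMS-spread
initialization, per-iteration closed-form Umeyama solve (via trimesh's
procrustes, reflection disabled) on the best 90% of matches, stopping
at 1e−6 relative RMS change or 50 iterations. Correspondences are
closest points on the target *surface* first — vertex-to-vertex
matching on coarsely sampled smooth meshes stalls in local minima
well inside a 20° misalignment, because the displacement exceeds the
vertex spacing — followed by a vertex-matching stage that snaps exact
correspondences once close; the transform with the lower trimmed
surface RMS is kept. Scale is solved by default: monocular
weak-perspective reconstruction has no absolute scale, so validation
should not penalize global size (disable with `allow_scale=False`).

## Synthetic data

The generators replace scan corpora, landmark detectors and sensor
references while preserving the statistical structure each stage
assumes:

- **Truth model**: a triangulated ellipsoid head (~180 x 220 x 150 mm;
  Fibonacci-sphere sampling + convex hull, so any vertex count works),
  with k orthonormal smooth modes (random degree-≤2 spherical-harmonic
  displacement fields, QR-orthonormalized) and SDs log-spaced 5 mm
  down to 0.5 mm. 68 landmark vertices sit at schematic facial
  positions (jaw rim, brows, nose, two eye rings, two mouth rings)
  following the common 68-slot annotation layout, so group-weighted
  losses and eye-closure terms are exercisable.
- **Subjects**: α ~ N(0, coeff_scale²) i.i.d., the Gaussian population
  implicit in PCA shape models.
- **Observations**: SOP projections of the landmark vertices plus
  i.i.d. Gaussian pixel noise, default 1 px (detector-level noise).
  Noise is `sd × standard_draw(seed)`, so different noise levels under
  one seed are paired (common random numbers) — this makes the
  noise-monotonicity checks near-deterministic rather than relying on
  large Monte-Carlo samples.
- **References**: "kinect" mode displaces vertices along normals with
  ~1 mm Gaussian noise (consumer depth sensor at ~1 m); "mri" mode
  applies a 0.3 mm smooth bias field plus 0.1 mm jitter
  (segmentation-scale artefacts).
- **Poses**: near-frontal, rotation ≤ 20°, scale 2–4 px/mm.

Scenario defaults (4 subjects, 1 px, 1 mm) mirror a small clinical
validation study. All generators are pure functions of their seeds.

What the generator does **not** emulate: real facial texture and
photometric appearance, detector bias (noise here is unbiased and
isotropic), occlusion and missing data (e.g. jaw regions invisible in
frontal views), non-Gaussian population structure, and clinical
asymmetry patterns. Passing synthetic tests therefore demonstrates
the correctness and numerical behaviour of the algorithms, not
clinical accuracy on patient data.

## Problem sizes and numerical choices

Tests and the acceptance script use heads of 220–300 vertices with
6–10 modes and 68 landmarks, 20-scenario/20-rep Monte-Carlo loops, and
200 randomized oracle instances — sizes chosen so the full suite runs
in a few minutes while every code path (including the O(points x
triangles) exact distance code) is exercised at scale-invariant
precision. Tolerances: orthonormality 1e−8; exact-recovery checks
1e−6 rad / 1e−8 relative scale; distance-oracle agreement 1e−10;
noiseless end-to-end surface error < 0.1 mm. Ties in SVD sign are
fixed deterministically; degenerate inputs (collinear correspondences,
empty masks, zero-norm features, rank-deficient unregularized systems)
raise typed errors rather than returning garbage.

## Known limitations

- The landmark fitter assumes a weak-perspective camera; strong
  perspective at close range is out of scope.
- Ridge-regularized fits are biased toward the mean shape; for
  noiseless or low-noise data reduce λ.
- ICP registration assumes a coarse pre-alignment (within ~20°); it
  does not attempt global registration.
- Distance computation is exact but O(points × triangles); it is sized
  for validation meshes (10³–10⁴ elements), not dense scans.
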