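"""Analytic components of the two deep reconstruction pipelines.

These are the *model and loss* pieces — evaluable scoring functions — of
(a) an articulated blendshape head model with linear blend skinning and
(b) a dual identity/expression/texture 3DMM with spherical-harmonics
shading.  Network training, rendering and landmark detection are outside
this package; images, masks, deep-feature vectors and displacement maps
enter as supplied arrays.

Conventions worth noting:

* The photometric loss uses the *un-squared* per-pixel l2 norm over
  channels, attention-weighted and averaged over the masked region.
  (Many re-implementations square it; here the un-squared form is the
  definition.)
* Default landmark weights are 20 on mouth and nose slots and 0
  elsewhere; both are overridable.
* The coefficient regularizer defaults to weights (1.0, 0.8, 0.0017) for
  the identity, expression and texture coefficient blocks.
* The spherical-harmonics shading uses the real SH basis, bands 0-2
  (9 functions); the constant table below is the single source of truth
  shared with the test oracle.
* The aggregate coarse/detail losses are unweighted sums of their named
  components; per-term weights are configurable.  The MRF detail term is
  defined externally and enters as a supplied scalar (default 0).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import InvalidInputError, MissingTermError, UndefinedLossError
from .landmarks import default_landmark_weights
from .mesh import TriangleMesh

__all__ = [
    "ArticulatedModel",
    "articulated_deform",
    "dual_3dmm",
    "SH_CONSTANTS",
    "sh_basis",
    "sh_radiosity",
    "photometric_loss",
    "landmark_loss",
    "perception_loss",
    "coef_reg_loss",
    "texture_flatten_loss",
    "eye_closure_loss",
    "shape_consistency_loss",
    "symmetry_loss",
    "detail_reg_loss",
    "coarse_loss",
    "detail_loss",
]


# ---------------------------------------------------------------------------
# articulated (FLAME-style) head model


@dataclasses.dataclass
class ArticulatedModel:
    """Articulated blendshape head model.

    ``template`` is the rest shape vector (3n,).  ``shape_basis`` /
    ``expr_basis`` are 3n x |beta| and 3n x |psi| blendshape matrices;
    ``pose_basis`` is 3n x 9k (pose correctives, driven by the flattened
    per-joint ``rotation - identity`` feature).  ``joints`` holds k joint
    positions (k = 4: neck, jaw, two eyeballs) with ``parents`` indices
    (-1 = attached to the global root).  ``skin_weights`` is k x n; each
    vertex's column is a convex combination.
    """

    template: np.ndarray
    shape_basis: np.ndarray
    pose_basis: np.ndarray
    expr_basis: np.ndarray
    joints: np.ndarray
    parents: np.ndarray
    skin_weights: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float).reshape(-1)
        self.shape_basis = np.asarray(self.shape_basis, dtype=float)
        self.pose_basis = np.asarray(self.pose_basis, dtype=float)
        self.expr_basis = np.asarray(self.expr_basis, dtype=float)
        self.joints = np.asarray(self.joints, dtype=float)
        self.parents = np.asarray(self.parents, dtype=np.int64).reshape(-1)
        self.skin_weights = np.asarray(self.skin_weights, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        n3 = self.template.size
        if n3 % 3:
            raise InvalidInputError("template length must be divisible by 3")
        n = n3 // 3
        k = len(self.joints)
        if self.joints.shape != (k, 3):
            raise InvalidInputError("joints must be (k, 3)")
        if self.parents.shape != (k,):
            raise InvalidInputError("parents must be (k,)")
        if self.pose_basis.size and self.pose_basis.shape != (n3, 9 * k):
            raise InvalidInputError("pose_basis must be 3n x 9k")
        if self.skin_weights.shape != (k, n):
            raise InvalidInputError("skin_weights must be (k, n)")
        if np.any(self.skin_weights < -1e-12):
            raise InvalidInputError("skin weights must be non-negative")
        if not np.allclose(self.skin_weights.sum(axis=0), 1.0, atol=1e-8):
            raise InvalidInputError("skin weight columns must sum to 1")

    @property
    def n_vertices(self) -> int:
        return self.template.size // 3

    @property
    def n_joints(self) -> int:
        return len(self.joints)


def _joint_rotations(theta: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(theta, dtype=float).reshape(-1)
    if theta.size != 3 * k + 3:
        raise InvalidInputError(f"theta must have length {3 * k + 3}")
    R_global = Rotation.from_rotvec(theta[:3]).as_matrix()
    R_joints = Rotation.from_rotvec(theta[3:].reshape(k, 3)).as_matrix()
    return R_global, R_joints


def pose_feature(theta: np.ndarray, k: int) -> np.ndarray:
    """Linearized pose-corrective feature: per-joint (R - I) flattened, (9k,)."""
    _, R_joints = _joint_rotations(theta, k)
    return (R_joints - np.eye(3)).reshape(-1)


def articulated_deform(
    model: ArticulatedModel,
    beta: np.ndarray,
    psi: np.ndarray,
    theta: np.ndarray,
) -> TriangleMesh:
    """Blendshapes + linear blend skinning.

    The rest-pose shape is ``T + S beta + P pose_feature(theta) + E psi``;
    it is then skinned: each joint's world transform is its parent's
    composed with a rotation about the joint position, the global rotation
    (first three entries of theta, about the origin) acting as the root,
    and vertices blend the joint transforms with ``skin_weights``.

    At ``theta = 0`` the output is the rest-pose shape exactly; a pure
    global rotation moves every vertex rigidly.
    """
    beta = np.asarray(beta, dtype=float).reshape(-1)
    psi = np.asarray(psi, dtype=float).reshape(-1)
    k = model.n_joints
    if beta.size != model.shape_basis.shape[1]:
        raise InvalidInputError("beta length does not match shape_basis")
    if psi.size != model.expr_basis.shape[1]:
        raise InvalidInputError("psi length does not match expr_basis")
    R_global, R_joints = _joint_rotations(theta, k)

    shaped = model.template + model.shape_basis @ beta + model.expr_basis @ psi
    if model.pose_basis.size:
        shaped = shaped + model.pose_basis @ pose_feature(theta, k)
    v = shaped.reshape(-1, 3)

    # rest pose: all transforms are the identity, skinning is a no-op
    if not np.any(np.asarray(theta, dtype=float)):
        return TriangleMesh(v, model.faces)

    # world affine transform (R, t) per joint; root is the global rotation
    world: list[tuple[np.ndarray, np.ndarray]] = [None] * k  # type: ignore
    def resolve(i: int) -> tuple[np.ndarray, np.ndarray]:
        if world[i] is not None:
            return world[i]
        Ri = R_joints[i]
        local = (Ri, model.joints[i] - Ri @ model.joints[i])
        p = model.parents[i]
        Rp, tp = (R_global, np.zeros(3)) if p < 0 else resolve(p)
        world[i] = (Rp @ local[0], Rp @ local[1] + tp)
        return world[i]

    out = np.zeros_like(v)
    for i in range(k):
        Ri, ti = resolve(i)
        out += model.skin_weights[i][:, None] * (v @ Ri.T + ti)
    return TriangleMesh(out, model.faces)


# ---------------------------------------------------------------------------
# dual identity/expression/texture 3DMM


def dual_3dmm(mean_shape, mean_tex, Bid, Bexp, Bt, alpha, beta, delta):
    """Linear dual 3DMM: S = S0 + Bid a + Bexp b, T = T0 + Bt d."""
    mean_shape = np.asarray(mean_shape, dtype=float)
    mean_tex = np.asarray(mean_tex, dtype=float)
    Bid, Bexp, Bt = (np.asarray(B, dtype=float) for B in (Bid, Bexp, Bt))
    alpha, beta, delta = (
        np.asarray(c, dtype=float).reshape(-1) for c in (alpha, beta, delta)
    )
    for B, c, name in ((Bid, alpha, "Bid"), (Bexp, beta, "Bexp"), (Bt, delta, "Bt")):
        if B.shape[1] != c.size:
            raise InvalidInputError(f"{name} has {B.shape[1]} columns, "
                                    f"got {c.size} coefficients")
    if Bid.shape[0] != mean_shape.size or Bexp.shape[0] != mean_shape.size:
        raise InvalidInputError("shape basis row count mismatch")
    if Bt.shape[0] != mean_tex.size:
        raise InvalidInputError("texture basis row count mismatch")
    shape = mean_shape + Bid @ alpha + Bexp @ beta
    texture = mean_tex + Bt @ delta
    return shape, texture


# ---------------------------------------------------------------------------
# spherical-harmonics shading

#: Real spherical-harmonics constants, bands 0-2 (the usual normalization
#: with the basis-function constants folded in).  Single source of truth
#: for both :func:`sh_basis` and its test oracle.
SH_CONSTANTS: dict[str, float] = {
    "c0": 0.28209479177387814,   # 1/2 * sqrt(1/pi)
    "c1": 0.4886025119029199,    # sqrt(3 / (4 pi))
    "c2": 1.0925484305920792,    # 1/2 * sqrt(15 / pi)
    "c3": 0.31539156525252005,   # 1/4 * sqrt(5 / pi)
    "c4": 0.5462742152960396,    # 1/4 * sqrt(15 / pi)
}


def sh_basis(normals: np.ndarray) -> np.ndarray:
    """Real SH basis functions, bands 0-2, evaluated at unit normals.

    Returns an (n, 9) matrix in the order
    ``1, y, z, x, xy, yz, 3z^2-1, xz, x^2-y^2`` (with their constants).
    """
    n = np.asarray(normals, dtype=float)
    single = n.ndim == 1
    n = np.atleast_2d(n)
    if n.shape[1] != 3:
        raise InvalidInputError("normals must be (n, 3)")
    norms = np.linalg.norm(n, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise InvalidInputError("normals must be unit length (tol 1e-6)")
    x, y, z = n.T
    c = SH_CONSTANTS
    basis = np.column_stack(
        [
            np.full(len(n), c["c0"]),
            c["c1"] * y,
            c["c1"] * z,
            c["c1"] * x,
            c["c2"] * x * y,
            c["c2"] * y * z,
            c["c3"] * (3.0 * z**2 - 1.0),
            c["c2"] * x * z,
            c["c4"] * (x**2 - y**2),
        ]
    )
    return basis[0] if single else basis


def sh_radiosity(normals, texture, gamma) -> np.ndarray:
    """Per-vertex shaded color: t_i * sum_b gamma_b Phi_b(n_i).

    ``gamma`` has 9 entries per channel: shape (9,) for a single channel
    or (9, C); ``texture`` is (n,) or (n, C) accordingly.
    """
    basis = np.atleast_2d(sh_basis(normals))  # (n, 9)
    gamma = np.asarray(gamma, dtype=float)
    texture = np.asarray(texture, dtype=float)
    if gamma.shape[0] != 9:
        raise InvalidInputError("gamma must have 9 coefficients per channel")
    shading = basis @ gamma  # (n,) or (n, C)
    if texture.ndim != shading.ndim and texture.ndim == 2:
        raise InvalidInputError("texture/gamma channel mismatch")
    return texture * shading


# ---------------------------------------------------------------------------
# losses


def photometric_loss(I, I_rend, A, M) -> float:
    """Attention-weighted mean per-pixel l2 color difference over a region.

    ``M`` marks the re-projected face region (nonzero = inside), ``A`` is
    a per-pixel skin-attention weight in [0, 1].  The per-pixel norm is
    un-squared.
    """
    I = np.asarray(I, dtype=float)
    I_rend = np.asarray(I_rend, dtype=float)
    A = np.asarray(A, dtype=float)
    M = np.asarray(M)
    if I.shape != I_rend.shape:
        raise InvalidInputError("image shapes disagree")
    if A.shape != I.shape[:-1] and A.shape != I.shape:
        raise InvalidInputError("attention mask shape mismatch")
    if M.shape != A.shape:
        raise InvalidInputError("region mask shape mismatch")
    diff = np.linalg.norm(I - I_rend, axis=-1)  # per-pixel l2 over channels
    inside = M.astype(bool)
    mass = float(A[inside].sum())
    if not inside.any() or mass <= 0:
        raise UndefinedLossError("empty or zero-mass face region")
    return float((A[inside] * diff[inside]).sum() / mass)


def landmark_loss(q, q_proj, weights=None) -> float:
    """Weighted mean landmark reprojection distance (1/N) sum w_n ||q - q'||.

    Default weights (for 68 points) are 20 on mouth/nose slots, 0
    elsewhere.
    """
    q = np.asarray(q, dtype=float)
    q_proj = np.asarray(q_proj, dtype=float)
    if q.shape != q_proj.shape or q.ndim != 2:
        raise InvalidInputError("landmark arrays must be equal-shape (N, 2)")
    N = len(q)
    if N < 1:
        raise InvalidInputError("need at least one landmark")
    if weights is None:
        weights = default_landmark_weights(N)
    weights = np.asarray(weights, dtype=float).reshape(-1)
    if weights.size != N:
        raise InvalidInputError("weight count mismatch")
    d = np.linalg.norm(q - q_proj, axis=1)
    return float((weights * d).sum() / N)


def perception_loss(f_I, f_rend) -> float:
    """1 - cosine similarity of two deep-feature vectors; in [0, 2]."""
    f_I = np.asarray(f_I, dtype=float).reshape(-1)
    f_rend = np.asarray(f_rend, dtype=float).reshape(-1)
    if f_I.size != f_rend.size:
        raise InvalidInputError("feature vectors must have equal length")
    na, nb = np.linalg.norm(f_I), np.linalg.norm(f_rend)
    if na == 0 or nb == 0:
        raise UndefinedLossError("zero-norm feature vector")
    return float(1.0 - (f_I @ f_rend) / (na * nb))


def coef_reg_loss(alpha, beta, delta,
                  weights: Sequence[float] = (1.0, 0.8, 0.0017)) -> float:
    """Coefficient regularizer w_a ||a||^2 + w_b ||b||^2 + w_d ||d||^2."""
    alpha, beta, delta = (
        np.asarray(c, dtype=float).reshape(-1) for c in (alpha, beta, delta)
    )
    wa, wb, wd = weights
    return float(wa * alpha @ alpha + wb * beta @ beta + wd * delta @ delta)


def texture_flatten_loss(texture, region_ids) -> float:
    """Sum over r,g,b of the texture variance within a skin region."""
    texture = np.asarray(texture, dtype=float)
    region_ids = np.asarray(region_ids, dtype=np.int64).reshape(-1)
    if region_ids.size == 0:
        raise UndefinedLossError("empty skin region")
    if texture.ndim == 1:
        texture = texture[:, None]
    region = texture[region_ids]
    return float(region.var(axis=0).sum())


def eye_closure_loss(pred_points, detected_points,
                     eyelid_pairs: Sequence[tuple[int, int]]) -> float:
    """Sum over eyelid pairs of |dy_pred - dy_detected| (vertical gaps)."""
    pred = np.asarray(pred_points, dtype=float)
    det = np.asarray(detected_points, dtype=float)
    total = 0.0
    for up, lo in eyelid_pairs:
        total += abs(
            (pred[up, 1] - pred[lo, 1]) - (det[up, 1] - det[lo, 1])
        )
    return float(total)


def shape_consistency_loss(beta_a, beta_b) -> float:
    """||beta_a - beta_b||^2 across two images of the same subject."""
    d = np.asarray(beta_a, dtype=float).reshape(-1) - np.asarray(
        beta_b, dtype=float
    ).reshape(-1)
    return float(d @ d)


def symmetry_loss(displacement: np.ndarray) -> float:
    """Mean |D - hflip(D)| of a UV displacement map (soft symmetry)."""
    D = np.asarray(displacement, dtype=float)
    return float(np.mean(np.abs(D - D[..., ::-1])))


def detail_reg_loss(displacement: np.ndarray) -> float:
    """Squared Frobenius norm of the displacement map."""
    D = np.asarray(displacement, dtype=float)
    return float((D**2).sum())


def load_loss_inputs(path) -> dict[str, np.ndarray]:
    """Load loss inputs from an NPZ archive (arrays keyed by name)."""
    with np.load(str(path)) as data:
        return {k: data[k] for k in data.files}


def load_image(path) -> np.ndarray:
    """Load an 8-bit RGB image as a float array rescaled to [0, 1]."""
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"), dtype=float) / 255.0


def load_loss_weights(path) -> dict[str, float]:
    """Per-term aggregate-loss weights from a YAML mapping."""
    import yaml

    weights = yaml.safe_load(open(path)) or {}
    return {str(k): float(v) for k, v in weights.items()}


_COARSE_TERMS = (
    "landmark", "eye", "photometric", "identity", "shape_consistency",
    "regularization",
)
_DETAIL_TERMS = ("photometric_detail", "mrf", "symmetry", "regularization_detail")


def _aggregate(components: Mapping[str, float | None], terms,
               weights: Mapping[str, float] | None) -> float:
    weights = dict(weights or {})
    total = 0.0
    for name in terms:
        value = components.get(name)
        if value is None:
            raise MissingTermError(name)
        total += weights.get(name, 1.0) * float(value)
    return total


def coarse_loss(
    landmark=None, eye=None, photometric=None, identity=None,
    shape_consistency=None, regularization=None,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Coarse-stage aggregate: unweighted sum of its six named components.

    Every component must be supplied (as a scalar, typically computed by
    the loss functions in this module); a missing one raises
    :class:`MissingTermError` naming it.  Per-term weights default to 1.
    """
    return _aggregate(
        {
            "landmark": landmark,
            "eye": eye,
            "photometric": photometric,
            "identity": identity,
            "shape_consistency": shape_consistency,
            "regularization": regularization,
        },
        _COARSE_TERMS,
        weights,
    )


def detail_loss(
    photometric_detail=None, symmetry=None, regularization_detail=None,
    mrf: float = 0.0, weights: Mapping[str, float] | None = None,
) -> float:
    """Detail-stage aggregate; the MRF term is externally supplied
    (default 0)."""
    return _aggregate(
        {
            "photometric_detail": photometric_detail,
            "mrf": mrf,
            "symmetry": symmetry,
            "regularization_detail": regularization_detail,
        },
        _DETAIL_TERMS,
        weights,
    )
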