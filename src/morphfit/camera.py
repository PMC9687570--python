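"""Scaled orthographic projection and landmark-based morphable-model fitting.

The camera is weak-perspective: a face whose depth extent is small relative
to its distance (~1 m for a seated subject) projects, up to a single scale,
orthographically:

    SOP(p; R, t, s) = s * (R p)[0:2] + s * t ,

with rotation ``R`` (3x3), model-frame translation ``t`` (2,) and scale
``s`` (pixels per millimetre).  Image coordinates follow the usual raster
convention: origin top-left, x right, y down, pixel centres at integers.

Pose from known 3D points is the classical POS construction — solve the
2x3 affine camera by linear least squares, project to the nearest scaled
rotation via SVD — followed by a Gauss-Newton refinement ("POS with
iteration") that takes the estimate to the nonlinear least-squares optimum.

Shape from known pose is a linear ridge system in the SD-unit model
coefficients.  The full fitter alternates the two exact half-steps and the
combined cost

    E(alpha, R, t, s) = (1/L) sum_i ||x_i - SOP(v_i(alpha))||^2
                        + lambda ||alpha||^2

is non-increasing along the iteration.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from .exceptions import (
    CoplanarWarning,
    DegenerateGeometryError,
    InsufficientCorrespondencesError,
    InvalidInputError,
    SingularSystemError,
)
from .mesh import TriangleMesh
from .shape_model import MorphableModel, synthesize_shape

__all__ = [
    "Pose",
    "Landmarks2D",
    "FitConfig",
    "FitResult",
    "sop_project",
    "estimate_pose",
    "estimate_coeffs_given_pose",
    "fit_landmarks",
    "LandmarkFitter",
]


@dataclasses.dataclass
class Pose:
    """Scaled-orthographic camera pose.

    ``R`` is a proper rotation; ``t`` is the 2D translation in model units
    (millimetres — the projection applies ``s * t``, so the pixel-space
    offset is ``s t``); ``s`` is the scale in pixels per millimetre.
    """

    R: np.ndarray
    t: np.ndarray
    s: float

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float).reshape(-1)
        self.s = float(self.s)
        if self.R.shape != (3, 3) or not np.all(np.isfinite(self.R)):
            raise InvalidInputError("R must be a finite 3x3 matrix")
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=1e-7):
            raise InvalidInputError("R is not orthonormal")
        if np.linalg.det(self.R) < 0:
            raise InvalidInputError("R must be a proper rotation (det +1)")
        if self.t.shape != (2,) or not np.all(np.isfinite(self.t)):
            raise InvalidInputError("t must be a finite 2-vector")
        if not np.isfinite(self.s) or self.s <= 0:
            raise InvalidInputError("scale must be positive")

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(2), 1.0)


@dataclasses.dataclass
class Landmarks2D:
    """Detected 2D landmarks: ``points`` (L, 2) pixels and slot ``ids``."""

    points: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64).reshape(-1)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidInputError("points must be (L, 2)")
        if not np.all(np.isfinite(self.points)):
            raise InvalidInputError("landmark coordinates must be finite")
        if len(self.ids) != len(self.points):
            raise InvalidInputError("ids and points length mismatch")
        if len(np.unique(self.ids)) != len(self.ids):
            raise InvalidInputError("landmark ids must be distinct")

    def __len__(self) -> int:
        return len(self.points)


@dataclasses.dataclass
class FitConfig:
    """Fitting hyper-parameters: ridge weight, iteration and tolerance."""

    prior_weight: float = 1e-3
    max_iters: int = 100
    rel_tol: float = 1e-8
    init_alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.prior_weight < 0:
            raise InvalidInputError("prior_weight must be >= 0")
        if self.max_iters < 1:
            raise InvalidInputError("max_iters must be >= 1")
        if self.rel_tol <= 0:
            raise InvalidInputError("rel_tol must be > 0")


@dataclasses.dataclass
class FitResult:
    """Outcome of the alternating fit."""

    coeffs: np.ndarray
    pose: Pose
    cost_trace: np.ndarray
    converged: bool


def sop_project(points3d: np.ndarray, pose: Pose) -> np.ndarray:
    """Scaled orthographic projection of (n, 3) points to (n, 2) pixels."""
    p = np.asarray(points3d, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[1] != 3 or not np.all(np.isfinite(p)):
        raise InvalidInputError("points3d must be finite (n, 3)")
    out = pose.s * (p @ pose.R[:2].T + pose.t)
    return out[0] if single else out


def _reprojection_cost(points3d, points2d, pose) -> float:
    r = points2d - sop_project(points3d, pose)
    return float(np.mean(np.sum(r * r, axis=1)))


def _pos(points3d: np.ndarray, points2d: np.ndarray) -> Pose:
    """POS: affine least squares + projection to the nearest scaled rotation."""
    n = len(points3d)
    A = np.hstack([points3d, np.ones((n, 1))])
    theta, *_ = np.linalg.lstsq(A, points2d, rcond=None)
    M = theta[:3].T  # 2x3 ~ s * R[:2]
    u, svals, vt = np.linalg.svd(M, full_matrices=False)
    s = float(np.mean(svals))
    if s <= 0 or not np.isfinite(s):
        s = 1.0
    r12 = u @ vt
    R = np.vstack([r12, np.cross(r12[0], r12[1])])
    t = np.mean(points2d / s - points3d @ R[:2].T, axis=0)
    return Pose(R, t, s)


def _skew(q: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -q[2], q[1]], [q[2], 0.0, -q[0]], [-q[1], q[0], 0.0]]
    )


def _refine_pose(points3d, points2d, pose, max_iters=100, tol=1e-14) -> Pose:
    """Gauss-Newton on (rotation increment, t, s) to the local LS optimum."""
    R, t, s = pose.R.copy(), pose.t.copy(), pose.s
    n = len(points3d)
    best = (R, t, s)
    prev = np.inf
    for _ in range(max_iters):
        q = points3d @ R.T  # (n, 3) rotated points
        proj = s * (q[:, :2] + t)
        r = (points2d - proj).reshape(-1)
        cost = float(r @ r) / n
        if cost > prev:  # overshoot: revert to the last accepted pose
            R, t, s = best
            break
        if prev - cost < tol * max(prev, 1.0):
            break
        prev = cost
        best = (R, t, s)
        J = np.zeros((2 * n, 6))
        for i in range(n):
            Sk = _skew(q[i])
            J[2 * i : 2 * i + 2, 0:3] = s * Sk[:2]
            J[2 * i : 2 * i + 2, 3:5] = -s * np.eye(2)
            J[2 * i : 2 * i + 2, 5] = -(q[i, :2] + t)
        # linearize r(d) ~ r + J d and solve the Gauss-Newton step J d = -r
        d, *_ = np.linalg.lstsq(J, -r, rcond=None)
        R = Rotation.from_rotvec(d[0:3]).as_matrix() @ R
        t = t + d[3:5]
        s = max(s + d[5], 1e-12)
    return Pose(R, t, s)


def estimate_pose(points3d: np.ndarray, points2d: np.ndarray) -> Pose:
    """Pose from >= 4 known 2D-3D correspondences (POS + refinement).

    With exact scaled-orthographic data the true pose is recovered to
    numerical precision.  Collinear 3D points are rejected; coplanar sets
    are accepted with a warning (the affine step is rank deficient but the
    refinement disambiguates the minimum-norm solution).
    """
    points3d = np.asarray(points3d, dtype=float)
    points2d = np.asarray(points2d, dtype=float)
    if len(points3d) != len(points2d):
        raise InvalidInputError("correspondence count mismatch")
    if len(points3d) < 4:
        raise InsufficientCorrespondencesError(
            f"need >= 4 correspondences, got {len(points3d)}"
        )
    centered = points3d - points3d.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale0 = svals[0] if svals[0] > 0 else 1.0
    if svals[1] / scale0 < 1e-9:
        raise DegenerateGeometryError("3D correspondences are collinear")
    if svals[2] / scale0 < 1e-9:
        warnings.warn(
            "3D correspondences are coplanar; pose estimate may be fragile",
            CoplanarWarning,
        )
    pose = _pos(points3d, points2d)
    return _refine_pose(points3d, points2d, pose)


def estimate_coeffs_given_pose(
    model: MorphableModel,
    landmarks: Landmarks2D,
    pose: Pose,
    prior_weight: float = 1e-3,
) -> np.ndarray:
    """Ridge solution for SD-unit shape coefficients at a fixed pose.

    Minimizes (1/L) sum ||x_i - SOP(f0_i + sum_j B_ji sd_j a_j)||^2
    + prior_weight * ||a||^2 — a linear system, solved in closed form.
    """
    f0, B = _landmark_arrays(model, landmarks)
    L, k = len(landmarks), model.n_modes
    P = pose.s * pose.R[:2]  # 2x3
    design = np.empty((2 * L, k))
    for j in range(k):
        design[:, j] = (model.mode_sd[j] * B[j] @ P.T).reshape(-1)
    rhs = (landmarks.points - sop_project(f0, pose)).reshape(-1)
    gram = design.T @ design / L
    if prior_weight == 0:
        if np.linalg.matrix_rank(design) < k:
            raise SingularSystemError(
                "shape system is rank deficient with prior_weight=0; "
                "set prior_weight > 0"
            )
        return np.linalg.lstsq(design, rhs, rcond=None)[0]
    return np.linalg.solve(
        gram + prior_weight * np.eye(k), design.T @ rhs / L
    )


def _landmark_arrays(model: MorphableModel, landmarks: Landmarks2D):
    """Mean landmark positions (L,3) and mode fields (k,L,3), id-resolved.

    Landmark ids index slots of ``model.landmark_vertex_ids``.
    """
    ids = landmarks.ids
    if ids.max(initial=-1) >= len(model.landmark_vertex_ids) or ids.min(initial=0) < 0:
        raise InvalidInputError("landmark id does not map to a model slot")
    mean, basis = model.landmark_basis()
    return mean[ids], basis[:, ids, :]


def _fit_cost(model, landmarks, pose, alpha, lam) -> float:
    f0, B = _landmark_arrays(model, landmarks)
    pts = f0 + np.tensordot(model.mode_sd * alpha, B, axes=(0, 0))
    r = landmarks.points - sop_project(pts, pose)
    return float(np.mean(np.sum(r * r, axis=1)) + lam * alpha @ alpha)


def _joint_gn_step(model, landmarks, pose, alpha, lam):
    """One guarded joint Gauss-Newton step on (rotation, t, s, alpha).

    Accelerates the alternation, whose coupling between pose and the
    weakly-determined shape directions contracts only linearly.  The step
    minimizes the same cost (ridge term included as augmented residuals)
    and is accepted only if the cost decreases (backtracking halving),
    so the outer trace stays monotone.
    """
    f0, B = _landmark_arrays(model, landmarks)
    L, k = len(landmarks), model.n_modes
    R, t, s = pose.R, pose.t, pose.s
    v = f0 + np.tensordot(model.mode_sd * alpha, B, axes=(0, 0))
    q = v @ R.T
    r = (landmarks.points - s * (q[:, :2] + t)).reshape(-1)
    sqlam = np.sqrt(L * lam)
    r_aug = np.concatenate([r, sqlam * alpha])
    J = np.zeros((2 * L + k, 6 + k))
    for i in range(L):
        Sk = _skew(q[i])
        J[2 * i : 2 * i + 2, 0:3] = s * Sk[:2]
        J[2 * i : 2 * i + 2, 3:5] = -s * np.eye(2)
        J[2 * i : 2 * i + 2, 5] = -(q[i, :2] + t)
    RB = (B.reshape(-1, 3) @ R.T).reshape(k, L, 3)  # rotated mode fields
    for j in range(k):
        J[: 2 * L, 6 + j] = -s * model.mode_sd[j] * RB[j, :, :2].reshape(-1)
    J[2 * L :, 6:] = sqlam * np.eye(k)
    d, *_ = np.linalg.lstsq(J, -r_aug, rcond=None)
    base_cost = _fit_cost(model, landmarks, pose, alpha, lam)
    step = 1.0
    for _ in range(8):  # backtracking line search
        dR = Rotation.from_rotvec(step * d[0:3]).as_matrix() @ R
        dt = t + step * d[3:5]
        ds = s + step * d[5]
        da = alpha + step * d[6:]
        if ds > 0:
            cand = Pose(dR, dt, ds)
            if _fit_cost(model, landmarks, cand, da, lam) < base_cost:
                return cand, da
        step *= 0.5
    return pose, alpha


def fit_landmarks(
    model: MorphableModel,
    landmarks: Landmarks2D,
    config: FitConfig | None = None,
) -> FitResult:
    """Alternating pose/shape fit of the morphable model to 2D landmarks.

    Starts from alpha = 0 with pose estimated on the mean-shape landmark
    vertices, then iterates until the relative change of the combined
    cost drops below ``config.rel_tol`` or ``config.max_iters`` is
    reached.  Each iteration applies the pose half-step, the exact ridge
    shape half-step, and a guarded joint Gauss-Newton step that speeds up
    the weakly-coupled pose/shape directions.  Every step is accepted
    only if it does not increase the cost, so the recorded ``cost_trace``
    is non-increasing.
    """
    config = config or FitConfig()
    lam = config.prior_weight
    k = model.n_modes
    alpha = (
        np.zeros(k)
        if config.init_alpha is None
        else np.asarray(config.init_alpha, dtype=float).reshape(-1)
    )
    if alpha.size != k:
        raise InvalidInputError("init_alpha length mismatch")
    f0, B = _landmark_arrays(model, landmarks)

    def verts(a):
        return f0 + np.tensordot(model.mode_sd * a, B, axes=(0, 0))

    pose = estimate_pose(verts(alpha), landmarks.points)
    cost = _fit_cost(model, landmarks, pose, alpha, lam)
    trace = [cost]
    converged = False
    for _ in range(config.max_iters):
        alpha = estimate_coeffs_given_pose(model, landmarks, pose, lam)
        candidate = estimate_pose(verts(alpha), landmarks.points)
        if _fit_cost(model, landmarks, candidate, alpha, lam) <= _fit_cost(
            model, landmarks, pose, alpha, lam
        ):
            pose = candidate
        pose, alpha = _joint_gn_step(model, landmarks, pose, alpha, lam)
        cost = _fit_cost(model, landmarks, pose, alpha, lam)
        trace.append(cost)
        prev = trace[-2]
        if abs(prev - cost) < config.rel_tol * max(prev, 1e-12) or cost < 1e-18:
            converged = True
            break
    return FitResult(
        coeffs=alpha,
        pose=pose,
        cost_trace=np.asarray(trace),
        converged=converged,
    )


class LandmarkFitter(BaseEstimator):
    """Scikit-learn style wrapper around :func:`fit_landmarks`.

    Parameters mirror :class:`FitConfig`; ``fit`` accepts a
    :class:`Landmarks2D` (or an (L, 2) array, in which case slot ids
    0..L-1 are assumed) and exposes ``coeffs_``, ``pose_``,
    ``cost_trace_`` and ``converged_``.  ``predict`` returns the
    reconstructed full-resolution mesh.
    """

    def __init__(self, model: MorphableModel | None = None,
                 prior_weight: float = 1e-3, max_iters: int = 100,
                 rel_tol: float = 1e-8):
        self.model = model
        self.prior_weight = prior_weight
        self.max_iters = max_iters
        self.rel_tol = rel_tol

    def fit(self, X, y=None) -> "LandmarkFitter":
        if self.model is None:
            raise InvalidInputError("a MorphableModel must be supplied")
        if not isinstance(X, Landmarks2D):
            X = np.asarray(X, dtype=float)
            X = Landmarks2D(X, np.arange(len(X)))
        result = fit_landmarks(
            self.model,
            X,
            FitConfig(
                prior_weight=self.prior_weight,
                max_iters=self.max_iters,
                rel_tol=self.rel_tol,
            ),
        )
        self.coeffs_ = result.coeffs
        self.pose_ = result.pose
        self.cost_trace_ = result.cost_trace
        self.converged_ = result.converged
        self.result_ = result
        return self

    def predict(self, X=None) -> TriangleMesh:
        """Reconstructed mesh for the fitted coefficients."""
        return synthesize_shape(self.model, self.coeffs_)
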