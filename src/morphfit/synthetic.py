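"""Synthetic ground-truth generators for every pipeline stage.

Real corpora (laser-scan morphable-model training sets), landmark
detections and sensor reference scans are replaced by seeded generators
that emulate their statistical structure:

* a *truth* morphable model whose mean is a head-sized triangulated
  ellipsoid (~180 x 220 x 150 mm) and whose modes are smooth,
  low-spatial-frequency orthonormal displacement fields with log-spaced
  SDs from 5 mm down to 0.5 mm — the implicit low-rank Gaussian shape
  population behind PCA face models;
* subjects drawn as i.i.d. Gaussian SD-unit coefficients;
* 2D landmark observations: scaled-orthographic projections of the 68
  landmark vertices plus i.i.d. Gaussian pixel noise (detector noise,
  default 1 px);
* degraded reference meshes: "kinect" mode displaces vertices along
  their normals with ~1 mm Gaussian noise (typical consumer depth-sensor
  error at ~1 m); "mri" mode applies a smooth low-amplitude bias field
  (0.3 mm) plus 0.1 mm jitter (segmentation artefacts).

All generators are pure functions of their integer seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from .camera import Landmarks2D, Pose, sop_project
from .exceptions import InvalidInputError
from .landmarks import N_LANDMARKS, landmark_directions
from .mesh import TriangleMesh, flatten_mesh
from .shape_model import MorphableModel, _fix_signs, synthesize_shape

__all__ = [
    "TruthScenario",
    "make_truth_model",
    "sample_subject",
    "sample_pose",
    "observe_landmarks",
    "degrade_mesh",
    "make_scenario",
]

#: Semi-axes (x width, y height, z depth) of the head ellipsoid, mm.
HEAD_SEMI_AXES = np.array([90.0, 110.0, 75.0])


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n well-spread unit directions (golden-spiral construction)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = 2.0 * np.pi * i / phi
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _ellipsoid_mesh(m: int) -> tuple[TriangleMesh, np.ndarray]:
    """Triangulated ellipsoid with m vertices; returns (mesh, unit dirs)."""
    dirs = _fibonacci_sphere(m)
    # rotate spiral axis onto +y so the pole isn't at the face front
    dirs = dirs[:, [0, 2, 1]]
    vertices = dirs * HEAD_SEMI_AXES
    hull = ConvexHull(vertices)
    faces = hull.simplices.copy()
    # orient faces outward
    tri = vertices[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = np.einsum("ij,ij->i", normals, tri.mean(axis=1)) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return TriangleMesh(vertices, faces), dirs


def _smooth_fields(dirs: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k smooth per-vertex 3D displacement fields, flattened to (k, 3m).

    Each field is a random degree<=2 real-spherical-harmonic expansion in
    the vertex direction, independently per coordinate axis — smooth and
    low spatial frequency by construction.
    """
    from .extended import sh_basis

    basis = sh_basis(dirs)  # (m, 9)
    fields = np.empty((k, dirs.shape[0] * 3))
    for j in range(k):
        coeffs = rng.normal(size=(9, 3))
        fields[j] = (basis @ coeffs).reshape(-1)
    return fields


def make_truth_model(
    seed: int,
    m_vertices: int = 562,
    k_modes: int = 10,
    n_landmarks: int = N_LANDMARKS,
) -> MorphableModel:
    """Ground-truth morphable model on a synthetic head.

    ``m_vertices`` >= 50 vertices on a face-proportioned ellipsoid;
    ``k_modes`` in [1, 30] orthonormal smooth modes with SDs log-spaced
    from 5 mm to 0.5 mm; 68 landmark vertices placed at schematic facial
    positions on the front of the head.  Same seed, same model, bit for
    bit.
    """
    if m_vertices < 50:
        raise InvalidInputError("m_vertices must be >= 50")
    if not 1 <= k_modes <= 30:
        raise InvalidInputError("k_modes must be in [1, 30]")
    if n_landmarks > m_vertices:
        raise InvalidInputError(
            f"cannot place {n_landmarks} distinct landmarks on "
            f"{m_vertices} vertices"
        )
    rng = np.random.default_rng(seed)
    mesh, dirs = _ellipsoid_mesh(m_vertices)

    fields = _smooth_fields(dirs, k_modes, rng)
    q, _ = np.linalg.qr(fields.T)  # (3m, k) orthonormal
    basis = _fix_signs(q[:, :k_modes])
    mode_sd = np.geomspace(5.0, 0.5, k_modes) if k_modes > 1 else np.array([5.0])

    lm_dirs = landmark_directions()[:n_landmarks]
    ids: list[int] = []
    score = dirs @ lm_dirs.T  # (m, L) alignment of vertex dirs with slots
    for j in range(n_landmarks):
        order = np.argsort(-score[:, j])
        pick = next(int(v) for v in order if int(v) not in ids)
        ids.append(pick)

    return MorphableModel(
        mean_shape=flatten_mesh(mesh),
        basis=basis,
        mode_sd=mode_sd,
        landmark_vertex_ids=np.array(ids),
        faces=mesh.faces,
    )


def sample_subject(
    model: MorphableModel, coeff_scale: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, TriangleMesh]:
    """Draw a subject: alpha ~ N(0, coeff_scale^2) i.i.d., and its mesh."""
    if coeff_scale < 0:
        raise InvalidInputError("coeff_scale must be >= 0")
    rng = np.random.default_rng(seed)
    alpha = rng.normal(0.0, coeff_scale, model.n_modes)
    return alpha, synthesize_shape(model, alpha)


def sample_pose(
    seed: int,
    max_angle_deg: float = 20.0,
    scale_range: tuple[float, float] = (2.0, 4.0),
    trans_range_mm: float = 30.0,
) -> Pose:
    """Near-frontal scaled-orthographic pose (seated subject, ~1 m away)."""
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, np.radians(max_angle_deg))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    s = rng.uniform(*scale_range)
    t = rng.uniform(-trans_range_mm, trans_range_mm, size=2)
    return Pose(R, t, s)


def observe_landmarks(
    mesh: TriangleMesh,
    model: MorphableModel,
    pose: Pose,
    noise_sd_px: float = 1.0,
    seed: int = 0,
) -> Landmarks2D:
    """Noisy 2D detections of the model's landmark vertices on ``mesh``.

    Projects the landmark vertices of ``mesh`` with the scaled
    orthographic camera and adds i.i.d. Gaussian pixel noise.  The noise
    is ``sd * standard_draw(seed)``, so observations at different noise
    levels under the same seed share the same standardized perturbation
    (a paired, common-random-numbers design).
    """
    if noise_sd_px < 0:
        raise InvalidInputError("noise_sd_px must be >= 0")
    rng = np.random.default_rng(seed)
    pts3d = mesh.vertices[model.landmark_vertex_ids]
    pts = sop_project(pts3d, pose)
    pts = pts + noise_sd_px * rng.standard_normal(pts.shape)
    return Landmarks2D(pts, np.arange(len(pts)))


def _vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    return np.asarray(mesh.to_trimesh().vertex_normals, dtype=float)


def degrade_mesh(
    mesh: TriangleMesh,
    noise_sd_mm: float = 1.0,
    seed: int = 0,
    mode: str = "kinect",
) -> TriangleMesh:
    """Sensor-like corruption of a reference mesh.

    ``kinect``: i.i.d. Gaussian displacement along vertex normals with SD
    ``noise_sd_mm`` (default 1 mm).  ``mri``: smooth low-amplitude bias
    field (0.3 mm scaled by ``noise_sd_mm``) plus 0.1 mm jitter, both
    along normals.
    """
    if noise_sd_mm < 0:
        raise InvalidInputError("noise_sd_mm must be >= 0")
    if mode not in ("kinect", "mri"):
        raise InvalidInputError(f"unknown degradation mode {mode!r}")
    if noise_sd_mm == 0:
        return mesh.copy()
    rng = np.random.default_rng(seed)
    normals = _vertex_normals(mesh)
    if mode == "kinect":
        disp = noise_sd_mm * rng.standard_normal(mesh.n_vertices)
    else:
        from .extended import sh_basis

        dirs = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        field = sh_basis(dirs) @ rng.normal(size=9)
        field /= max(np.sqrt(np.mean(field**2)), 1e-30)  # unit-RMS smooth field
        disp = 0.3 * noise_sd_mm * field + 0.1 * rng.standard_normal(
            mesh.n_vertices
        )
    return TriangleMesh(mesh.vertices + disp[:, None] * normals, mesh.faces)


@dataclasses.dataclass
class TruthScenario:
    """A fully seeded synthetic experiment: model, subjects, noise levels."""

    truth_model: MorphableModel
    subjects: list[tuple[np.ndarray, Pose]]
    landmark_noise_sd: float
    mesh_noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.landmark_noise_sd < 0 or self.mesh_noise_sd < 0:
            raise InvalidInputError("noise SDs must be >= 0")


def make_scenario(
    seed: int,
    n_subjects: int = 4,
    m_vertices: int = 562,
    k_modes: int = 10,
    landmark_noise_sd: float = 1.0,
    mesh_noise_sd: float = 1.0,
    coeff_scale: float = 1.0,
    max_angle_deg: float = 20.0,
) -> TruthScenario:
    """Assemble a seeded scenario: truth model plus per-subject
    (coefficients, pose) draws.

    Defaults mirror the validation study's conditions: four subjects,
    near-frontal poses, ~1 px landmark detector noise and ~1 mm reference
    sensor noise.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=(n_subjects, 2))
    model = make_truth_model(
        int(rng.integers(0, 2**31 - 1)), m_vertices, k_modes
    )
    subjects = []
    for i in range(n_subjects):
        alpha, _ = sample_subject(model, coeff_scale, int(sub_seeds[i, 0]))
        pose = sample_pose(int(sub_seeds[i, 1]), max_angle_deg=max_angle_deg)
        subjects.append((alpha, pose))
    return TruthScenario(
        truth_model=model,
        subjects=subjects,
        landmark_noise_sd=landmark_noise_sd,
        mesh_noise_sd=mesh_noise_sd,
        seed=seed,
    )
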