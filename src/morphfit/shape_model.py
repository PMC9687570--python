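"""PCA statistical shape model (morphable model) of corresponded face meshes.

A morphable model represents a face population as a mean shape plus a
linear combination of orthonormal principal modes,

    S(alpha) = S0 + sum_j  B_j * sd_j * alpha_j ,

where ``S0`` is the mean shape vector, the ``B_j`` are unit-norm columns
of the PCA basis, ``sd_j`` are the per-mode standard deviations (singular
value / sqrt(n-1)) and the user-facing coefficients ``alpha`` are
dimensionless, expressed in units of ``sd_j``.  SD units make a Gaussian
(Mahalanobis) prior on alpha an isotropic ridge penalty during fitting.

The decomposition is a thin SVD of the centered (n, 3m) data matrix —
the 3m x 3m covariance is never formed.  Basis sign is fixed by making
each column's entry of largest magnitude positive, so repeated builds are
bit-stable.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    CorpusError,
    InvalidInputError,
    RankError,
    ZeroVarianceWarning,
)
from .mesh import TriangleMesh, flatten_mesh, unflatten, _check_shared_topology

__all__ = [
    "MorphableModel",
    "MorphableModelPCA",
    "build_morphable_model",
    "synthesize_shape",
    "project_coeffs",
    "save_model",
    "load_model",
]

_ORTHO_TOL = 1e-8


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (deterministic)."""
    idx = np.argmax(np.abs(basis), axis=0)
    signs = np.sign(basis[idx, np.arange(basis.shape[1])])
    signs[signs == 0] = 1.0
    return basis * signs


@dataclasses.dataclass
class MorphableModel:
    """A fitted PCA shape model.

    Attributes
    ----------
    mean_shape : (3m,) array, millimetres — the mean shape vector S0.
    basis : (3m, k) array with pairwise-orthonormal unit columns.
    mode_sd : (k,) array, millimetres; non-increasing per-mode SDs.
    landmark_vertex_ids : (L,) int array of distinct vertex indices.
    faces : (f, 3) face list shared by every synthesized mesh.
    """

    mean_shape: np.ndarray
    basis: np.ndarray
    mode_sd: np.ndarray
    landmark_vertex_ids: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=float).reshape(-1)
        self.basis = np.asarray(self.basis, dtype=float)
        self.mode_sd = np.asarray(self.mode_sd, dtype=float).reshape(-1)
        self.landmark_vertex_ids = np.asarray(
            self.landmark_vertex_ids, dtype=np.int64
        ).reshape(-1)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.mean_shape.size % 3 != 0 or not np.all(np.isfinite(self.mean_shape)):
            raise InvalidInputError("mean_shape must be a finite length-3m vector")
        if self.basis.shape != (self.mean_shape.size, self.mode_sd.size):
            raise InvalidInputError(
                f"basis shape {self.basis.shape} inconsistent with "
                f"mean {self.mean_shape.size} and k={self.mode_sd.size}"
            )
        k = self.mode_sd.size
        if k:
            gram = self.basis.T @ self.basis
            if not np.allclose(gram, np.eye(k), atol=1e-7):
                raise InvalidInputError("basis columns are not orthonormal")
            if np.any(self.mode_sd < 0) or np.any(np.diff(self.mode_sd) > 1e-12):
                raise InvalidInputError("mode_sd must be non-negative, non-increasing")
            if np.any(self.mode_sd <= 1e-12):
                warnings.warn(
                    "model has zero-variance modes", ZeroVarianceWarning
                )
        m = self.n_vertices
        ids = self.landmark_vertex_ids
        if ids.size:
            if ids.min() < 0 or ids.max() >= m:
                raise InvalidInputError("landmark vertex index out of range")
            if len(np.unique(ids)) != ids.size:
                raise InvalidInputError("landmark vertex ids must be distinct")

    @property
    def n_vertices(self) -> int:
        return self.mean_shape.size // 3

    @property
    def n_modes(self) -> int:
        return self.mode_sd.size

    @property
    def mean_mesh(self) -> TriangleMesh:
        return unflatten(self.mean_shape, self.faces)

    def landmark_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean positions (L, 3) and basis (k, L, 3) restricted to landmarks."""
        ids = self.landmark_vertex_ids
        mean = self.mean_shape.reshape(-1, 3)[ids]
        basis = self.basis.T.reshape(self.n_modes, -1, 3)[:, ids, :]
        return mean, basis


class MorphableModelPCA(TransformerMixin, BaseEstimator):
    """Scikit-learn style PCA shape-model estimator on flattened shapes.

    Parameters
    ----------
    n_components : int or None
        Number of modes k.  None keeps the smallest k explaining at least
        ``variance_threshold`` of the total variance.
    variance_threshold : float
        Explained-variance fraction used when ``n_components`` is None.

    Fitted attributes (all suffixed with an underscore): ``mean_``,
    ``components_`` (k, 3m) rows, ``mode_sd_``, ``singular_values_``,
    ``n_components_``, ``n_samples_``, ``total_variance_``.

    ``transform`` maps shape vectors to SD-unit coefficients,
    ``inverse_transform`` maps coefficients back to shape vectors.
    """

    def __init__(self, n_components: int | None = None,
                 variance_threshold: float = 0.99):
        self.n_components = n_components
        self.variance_threshold = variance_threshold

    def fit(self, X: np.ndarray, y=None) -> "MorphableModelPCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise CorpusError("need a 2-D data matrix with at least 2 samples")
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("corpus contains non-finite values")
        n = X.shape[0]
        self.mean_ = X.mean(axis=0)
        centered = X - self.mean_
        # thin SVD: n << 3m, never forms the covariance
        _, svals, vt = np.linalg.svd(centered, full_matrices=False)
        max_k = n - 1
        if self.n_components is None:
            var = svals[:max_k] ** 2
            total = var.sum()
            if total <= 0:
                k = max_k
            else:
                k = int(np.searchsorted(np.cumsum(var) / total,
                                        self.variance_threshold) + 1)
                k = min(k, max_k)
        else:
            k = int(self.n_components)
            if not 1 <= k <= max_k:
                raise RankError(
                    f"n_components={k} not in [1, n-1={max_k}]"
                )
        sd = svals[:k] / np.sqrt(n - 1)
        if np.any(sd <= 1e-12):
            warnings.warn(
                "corpus has (numerically) zero variance along requested "
                "modes; their SDs are 0",
                ZeroVarianceWarning,
            )
        self.components_ = _fix_signs(vt[:k].T).T
        self.singular_values_ = svals[:k]
        self.mode_sd_ = sd
        self.n_components_ = k
        self.n_samples_ = n
        self.total_variance_ = float((svals[: n - 1] ** 2).sum() / (n - 1))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.mean_.size:
            raise InvalidInputError(
                f"expected vectors of length {self.mean_.size}, got {X.shape[1]}"
            )
        scores = (X - self.mean_) @ self.components_.T
        sd = np.where(self.mode_sd_ > 0, self.mode_sd_, 1.0)
        alpha = scores / sd
        return alpha[0] if single else alpha

    def inverse_transform(self, alpha: np.ndarray) -> np.ndarray:
        alpha = np.asarray(alpha, dtype=float)
        single = alpha.ndim == 1
        alpha = np.atleast_2d(alpha)
        if alpha.shape[1] != self.n_components_:
            raise InvalidInputError(
                f"expected {self.n_components_} coefficients, got {alpha.shape[1]}"
            )
        X = self.mean_ + (alpha * self.mode_sd_) @ self.components_
        return X[0] if single else X


def build_morphable_model(
    corpus: Sequence[TriangleMesh],
    k: int | None = None,
    landmark_vertex_ids: Sequence[int] | None = None,
    variance_threshold: float = 0.99,
) -> MorphableModel:
    """Build a morphable model from a corresponded mesh corpus.

    All meshes must share vertex count and face list.  ``k`` defaults to
    the smallest mode count explaining >= ``variance_threshold`` of the
    variance; at most n-1 modes exist for n meshes.
    """
    _check_shared_topology(corpus)
    if len(corpus) < 2:
        raise CorpusError("need at least 2 meshes")
    X = np.stack([flatten_mesh(m) for m in corpus])
    est = MorphableModelPCA(n_components=k, variance_threshold=variance_threshold)
    est.fit(X)
    ids = np.asarray(
        landmark_vertex_ids if landmark_vertex_ids is not None else [],
        dtype=np.int64,
    )
    return MorphableModel(
        mean_shape=est.mean_,
        basis=est.components_.T,
        mode_sd=est.mode_sd_,
        landmark_vertex_ids=ids,
        faces=corpus[0].faces,
    )


def synthesize_shape(model: MorphableModel, coeffs: np.ndarray) -> TriangleMesh:
    """Evaluate the linear shape model at SD-unit coefficients ``coeffs``."""
    alpha = np.asarray(coeffs, dtype=float).reshape(-1)
    if alpha.size != model.n_modes:
        raise InvalidInputError(
            f"expected {model.n_modes} coefficients, got {alpha.size}"
        )
    if not np.all(np.isfinite(alpha)):
        raise InvalidInputError("coefficients contain non-finite values")
    vec = model.mean_shape + model.basis @ (model.mode_sd * alpha)
    return unflatten(vec, model.faces)


def project_coeffs(model: MorphableModel, mesh: TriangleMesh) -> np.ndarray:
    """Least-squares SD-unit coefficients of a mesh under the model.

    Exact inverse of :func:`synthesize_shape` for shapes in the model's
    span; for out-of-span shapes, returns the coefficients of the
    orthogonal projection onto the span.
    """
    if mesh.n_vertices != model.n_vertices:
        raise InvalidInputError(
            f"mesh has {mesh.n_vertices} vertices, model has {model.n_vertices}"
        )
    scores = model.basis.T @ (flatten_mesh(mesh) - model.mean_shape)
    sd = np.where(model.mode_sd > 0, model.mode_sd, 1.0)
    return scores / sd


def save_model(model: MorphableModel, path: str | Path) -> None:
    """Persist a model as a single NPZ archive with a JSON metadata block."""
    meta = {
        "n_vertices": model.n_vertices,
        "n_modes": model.n_modes,
        "units": "mm",
        "flattening": "interleaved-xyz-per-vertex",
    }
    np.savez_compressed(
        str(path),
        mean_shape=model.mean_shape,
        basis=model.basis,
        mode_sd=model.mode_sd,
        landmark_vertex_ids=model.landmark_vertex_ids,
        faces=model.faces,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path: str | Path) -> MorphableModel:
    with np.load(str(path)) as data:
        return MorphableModel(
            mean_shape=data["mean_shape"],
            basis=data["basis"],
            mode_sd=data["mode_sd"],
            landmark_vertex_ids=data["landmark_vertex_ids"],
            faces=data["faces"],
        )
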