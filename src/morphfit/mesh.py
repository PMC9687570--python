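"""Triangle meshes, the flattening convention, and mesh file I/O.

All geometry in this package lives in millimetres.  A shape vector is the
per-vertex interleaved flattening ``(x1, y1, z1, ..., xm, ym, zm)`` of a
mesh's vertices; every module uses this one convention.

File I/O is delegated to :mod:`trimesh` with ``process=False`` so that
vertex order — the correspondence that morphable models rely on — is never
silently altered.  STL files store one vertex triplet per facet and destroy
shared indexing, so they are accepted only for validation meshes, never for
model-building corpora.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh

from .exceptions import InvalidInputError, CorpusError

__all__ = [
    "TriangleMesh",
    "flatten_mesh",
    "unflatten",
    "load_mesh",
    "save_mesh",
    "load_corpus",
]


@dataclasses.dataclass
class TriangleMesh:
    """A triangle mesh: ``vertices`` (m, 3) in millimetres, ``faces`` (f, 3).

    Invariants enforced on construction: finite coordinates, face indices in
    ``[0, m)`` and no degenerate face (three distinct indices per face).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidInputError(
                f"vertices must be (m, 3), got {self.vertices.shape}"
            )
        if not np.all(np.isfinite(self.vertices)):
            raise InvalidInputError("mesh vertices contain non-finite values")
        if self.faces.size:
            if self.faces.ndim != 2 or self.faces.shape[1] != 3:
                raise InvalidInputError(
                    f"faces must be (f, 3), got {self.faces.shape}"
                )
            m = len(self.vertices)
            if self.faces.min() < 0 or self.faces.max() >= m:
                raise InvalidInputError("face index out of range")
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise InvalidInputError("degenerate face (repeated vertex index)")
        else:
            self.faces = self.faces.reshape(0, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


def flatten_mesh(mesh: TriangleMesh) -> np.ndarray:
    """Flatten a mesh to its shape vector ``(x1, y1, z1, ..., xm, ym, zm)``.

    A mesh with m vertices yields a vector of length 3m.  Exact inverse
    of :func:`unflatten`.
    """
    if not isinstance(mesh, TriangleMesh):
        mesh = TriangleMesh(np.asarray(mesh), np.empty((0, 3), dtype=np.int64))
    return mesh.vertices.reshape(-1).copy()


def unflatten(vec: np.ndarray, faces: np.ndarray) -> TriangleMesh:
    """Rebuild a mesh from a shape vector and a face list.

    ``flatten_mesh(unflatten(v, faces))`` equals ``v`` exactly.
    """
    vec = np.asarray(vec, dtype=float)
    if vec.ndim != 1:
        raise InvalidInputError("shape vector must be one-dimensional")
    if vec.size % 3 != 0:
        raise InvalidInputError(
            f"shape vector length {vec.size} is not divisible by 3"
        )
    return TriangleMesh(vec.reshape(-1, 3), np.asarray(faces, dtype=np.int64))


def load_mesh(path: str | Path, scale: float = 1.0) -> TriangleMesh:
    """Load an OBJ/PLY/STL mesh, multiplying coordinates by ``scale``.

    Coordinates are taken as-is (millimetres expected); meshes authored in
    metres can be converted with ``scale=1000``.
    """
    tm = trimesh.load(str(path), process=False, force="mesh")
    return TriangleMesh(np.asarray(tm.vertices, dtype=float) * float(scale),
                        np.asarray(tm.faces, dtype=np.int64))


def save_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh; the format follows the file extension (.obj/.ply/.stl)."""
    mesh.to_trimesh().export(str(path))


def load_corpus(paths: Iterable[str | Path], scale: float = 1.0) -> list[TriangleMesh]:
    """Load a corresponded corpus, rejecting STL inputs.

    STL duplicates vertices per facet, which destroys the shared vertex
    indexing a corpus requires, so it is refused here (use PLY or OBJ).
    All meshes must share vertex count and face list.
    """
    meshes = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() == ".stl":
            raise CorpusError(
                f"{p}: STL destroys shared vertex indexing and cannot be "
                "used for a corpus (accepted only for validation meshes)"
            )
        meshes.append(load_mesh(p, scale=scale))
    _check_shared_topology(meshes)
    return meshes


def _check_shared_topology(meshes: Sequence[TriangleMesh]) -> None:
    if not meshes:
        raise CorpusError("empty corpus")
    m0, f0 = meshes[0].n_vertices, meshes[0].faces
    for i, mesh in enumerate(meshes[1:], start=1):
        if mesh.n_vertices != m0:
            raise CorpusError(
                f"mesh {i} has {mesh.n_vertices} vertices, expected {m0}"
            )
        if mesh.faces.shape != f0.shape or not np.array_equal(mesh.faces, f0):
            raise CorpusError(f"mesh {i} face list differs from mesh 0")
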