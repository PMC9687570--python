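"""Shared fixtures: small deterministic meshes and a truth shape model."""

import numpy as np
import pytest

from morphfit import TriangleMesh, make_truth_model
from morphfit.synthetic import _ellipsoid_mesh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tetra():
    """A regular-ish tetrahedron, handy for exact hand-checked cases."""
    vertices = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return TriangleMesh(vertices, faces)


@pytest.fixture(scope="session")
def truth_model():
    """Session-wide synthetic truth model (small head, 8 modes)."""
    return make_truth_model(seed=11, m_vertices=300, k_modes=8)


@pytest.fixture(scope="session")
def head_mesh():
    mesh, _ = _ellipsoid_mesh(200)
    return mesh


def random_mesh(rng, n_vertices=20, n_faces=30, scale=10.0):
    """A random valid triangle soup (not watertight; fine for distances)."""
    vertices = rng.normal(0.0, scale, (n_vertices, 3))
    faces = []
    while len(faces) < n_faces:
        f = rng.choice(n_vertices, 3, replace=False)
        faces.append(f)
    return TriangleMesh(vertices, np.array(faces))
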