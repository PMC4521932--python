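import numpy as np
import pytest

from cbflat.mesh_core import FlatMesh, TriangleMesh
from cbflat.synthetic import SynthSpec, make_folded_pair


@pytest.fixture
def unit_square_flat():
    """Two-triangle unit square in the plane, CCW winding."""
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return FlatMesh(coords, faces)


@pytest.fixture
def grid_mesh_factory():
    """Regular n x n planar grid as a 3D TriangleMesh (z = 0)."""

    def make(n: int, spacing: float = 1.0) -> TriangleMesh:
        idx = np.arange(n * n).reshape(n, n)
        xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing,
                             indexing="ij")
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                v00, v10 = idx[i, j], idx[i + 1, j]
                v11, v01 = idx[i + 1, j + 1], idx[i, j + 1]
                faces += [[v00, v10, v11], [v00, v11, v01]]
        return TriangleMesh(verts, np.array(faces))

    return make


@pytest.fixture(scope="session")
def small_spec():
    return SynthSpec(mesh_shape=(25, 13))


@pytest.fixture(scope="session")
def small_sheet(small_spec):
    """Folded sheet at reduced mesh resolution; (pair, grey, flat, shares)."""
    return make_folded_pair(small_spec)


@pytest.fixture(scope="session")
def default_spec():
    return SynthSpec()


@pytest.fixture(scope="session")
def default_sheet(default_spec):
    return make_folded_pair(default_spec)


@pytest.fixture
def center_square_problem():
    """Unit square with one free center vertex and four faces."""
    from cbflat.flatten import FlattenProblem

    coords = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0],
                       [0.5, 0.5]])
    faces = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]])
    flat0 = FlatMesh(coords, faces)
    targets = np.array([0.3, 0.3, 0.2, 0.2])
    fixed = np.array([True, True, True, True, False])
    return FlattenProblem(flat0, targets, fixed)
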