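import numpy as np
import pytest
import trimesh

from patchap.mesh import TriangleMesh
from patchap.simulate import make_synthetic_head


@pytest.fixture(scope="session")
def icosahedron() -> TriangleMesh:
    m = trimesh.creation.icosahedron()
    return TriangleMesh(vertices=np.asarray(m.vertices) * 100.0,
                        faces=np.asarray(m.faces))


@pytest.fixture(scope="session")
def ico1_mesh() -> TriangleMesh:
    """42-vertex icosphere: small enough for brute-force oracles."""
    m = trimesh.creation.icosphere(subdivisions=1, radius=100.0)
    return TriangleMesh(vertices=np.asarray(m.vertices),
                        faces=np.asarray(m.faces))


@pytest.fixture(scope="session")
def head23():
    """Default small dual-resolution head: 162 sim / 642 inv vertices."""
    return make_synthetic_head(levels=(2, 3), m=128, seed=7)


@pytest.fixture(scope="session")
def head_small():
    """Single-resolution 42-vertex head for unit tests (inverse crime OK)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_synthetic_head(levels=(1, 1), m=32, seed=11)


@pytest.fixture()
def path_graph_adjacency():
    import scipy.sparse as sp

    def make(n: int):
        a = sp.diags([np.ones(n - 1), np.ones(n - 1)], [1, -1])
        return sp.csr_matrix(a)

    return make
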