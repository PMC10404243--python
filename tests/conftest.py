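import numpy as np
import pytest
from shapely.geometry import Polygon

from stlgcp import assemble_fem, build_mesh, dual_weights


@pytest.fixture(scope="session")
def unit_square():
    return Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture(scope="session")
def square_mesh(unit_square):
    """Unit-square mesh without extension ring, reused across tests."""
    return build_mesh(unit_square, 0.2, extension_fraction=0.0)


@pytest.fixture(scope="session")
def square_fem(square_mesh):
    return assemble_fem(square_mesh)


@pytest.fixture(scope="session")
def square_weights(square_mesh, unit_square):
    return dual_weights(square_mesh, unit_square)


@pytest.fixture(scope="session")
def two_triangle_mesh(unit_square):
    """Unit square split along the diagonal (0,0)-(1,1): the classic
    four-vertex FEM hand-check geometry."""
    from stlgcp.mesh import Mesh

    verts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    return Mesh(vertices=verts, triangles=tris, boundary=unit_square,
                interior_mask=np.ones(4, dtype=bool))
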