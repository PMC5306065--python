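import numpy as np
import pytest

from lamsim.ogden import OgdenParameters


@pytest.fixture(scope="session")
def default_params():
    return OgdenParameters.default()


@pytest.fixture(scope="session")
def two_tet_mesh():
    """Minimal two-tetrahedron deformable fixture (4 mm scale)."""
    from lamsim.anatomy import LabeledTetMesh

    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                      [0, 0, 1], [1, 1, 1.]]) * 4.0
    tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    return LabeledTetMesh(nodes, tets, np.zeros(2, np.int8), {})


def rotation_matrix(seed=0):
    """Random proper rotation for objectivity checks."""
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()
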