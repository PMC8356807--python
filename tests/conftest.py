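import numpy as np
import pytest
import scipy.sparse as sp

from wmdss.graph import EdgeWeightParams, build_wm_graph
from wmdss.odf import AnalyticODFField
from wmdss.phantoms import make_circular_phantom


def single_fiber_field(shape=(5, 5, 5), axis=(1.0, 0.0, 0.0), kappa=5.0,
                       floor=0.1, voxel_size_mm=1.25):
    """Uniform single-fiber analytic ODF field plus isotropic floor."""
    shape = tuple(shape)
    mask = np.ones(shape, dtype=bool)
    axes = np.zeros(shape + (1, 3))
    axes[...] = np.asarray(axis, dtype=float) / np.linalg.norm(axis)
    return AnalyticODFField(mask, axes, np.full(shape + (1,), kappa),
                            np.ones(shape + (1,)), floor, voxel_size_mm)


def random_connected_graph(n, density=0.02, seed=0):
    """Random symmetric weighted graph, guaranteed connected via a path."""
    rng = np.random.default_rng(seed)
    A = sp.random(n, n, density=density, rng=rng)
    A = A + A.T
    i = np.arange(n - 1)
    path = sp.coo_matrix((rng.random(n - 1) + 0.1, (i, i + 1)), shape=(n, n))
    A = (A + path + path.T).tolil()
    A.setdiag(0)
    return A.tocsr()


@pytest.fixture(scope="session")
def fiber_field_5cube():
    return single_fiber_field((5, 5, 5))


@pytest.fixture(scope="session")
def fiber_graph_5cube(fiber_field_5cube):
    return build_wm_graph(fiber_field_5cube, ndef="5-conn",
                          params=EdgeWeightParams(alpha=0.9, beta=50.0))


@pytest.fixture(scope="session")
def circular_phantom_small():
    return make_circular_phantom([0.0, 0.0, 1.0], 10, shape=(32, 32, 32))
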