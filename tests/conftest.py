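import numpy as np
import pytest

from vesimeso import elasticity as el
from vesimeso import meshgen as mg


@pytest.fixture(scope="session")
def emb_mesh():
    """162-vertex icosphere, radius 2 (the small test shell)."""
    return mg.icosphere(2, 2.0)


@pytest.fixture(scope="session")
def emb_material():
    return el.emb_material(E2d=2000.0, nu=1.0 / 3.0, h=0.25)


@pytest.fixture(scope="session")
def gv_small():
    """Small GV capsule (128 vertices) with its rib field."""
    mesh = mg.gv_capsule(1.2, 4.0, n_ring=12, ring_spacing=0.5,
                         cone_ring_sizes=(6, 3))
    rib = mg.rib_direction_field(mesh, [0.0, 0.0, 1.0])
    return mesh, rib


@pytest.fixture(scope="session")
def gv_small_material():
    eng = el.OrthotropicEngineering(E_l=2000.0, E_t=1000.0, nu_lt=0.2,
                                    G=375.0, h=0.42)
    return el.gv_material(eng)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
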