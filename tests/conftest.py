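import numpy as np
import pytest

from precmap import make_icosphere, make_templates


@pytest.fixture(scope="session")
def mesh_small():
    """Level-2 icosphere (162 vertices, radius 50 mm)."""
    return make_icosphere(2, 50.0)


@pytest.fixture(scope="session")
def mesh_mid():
    """Level-3 icosphere (642 vertices, radius 50 mm)."""
    return make_icosphere(3, 50.0)


@pytest.fixture(scope="session")
def template_small(mesh_small):
    """Four flat-top network templates on the small mesh."""
    return make_templates(mesh_small, n_networks=4, smoothness_mm=18.0,
                          var_scale=0.05, seed=3)


@pytest.fixture(scope="session")
def template_mid(mesh_mid):
    return make_templates(mesh_mid, n_networks=4, smoothness_mm=18.0,
                          var_scale=0.05, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
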