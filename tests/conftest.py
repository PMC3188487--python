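import numpy as np
import pytest

from prscan.enm import ElasticNetworkModel
from prscan.fixtures import FixtureSpec, make_fixture

# geometries used across the suite: everything non-collinear gets the full
# spectrum/oracle treatment, the linear chain exercises the degenerate path
NONDEGENERATE_SPECS = {
    "two_mass": FixtureSpec(kind="two_mass", n_residues=2, spacing=3.8),
    "triangle": FixtureSpec(kind="ring", n_residues=3, spacing=3.8),
    "helix12": FixtureSpec(kind="ideal_helix", n_residues=12),
    "helix20": FixtureSpec(kind="ideal_helix", n_residues=20),
    "cloud6": FixtureSpec(kind="random_cloud", n_residues=6, spacing=3.8, seed=3),
    "cloud10": FixtureSpec(kind="random_cloud", n_residues=10, spacing=3.8, seed=1),
}


@pytest.fixture(params=sorted(NONDEGENERATE_SPECS), ids=sorted(NONDEGENERATE_SPECS))
def any_model(request):
    return make_fixture(NONDEGENERATE_SPECS[request.param])


@pytest.fixture(scope="session")
def helix():
    return make_fixture(FixtureSpec(kind="ideal_helix", n_residues=20))


@pytest.fixture(scope="session")
def helix_enm(helix):
    return ElasticNetworkModel().fit(helix)


@pytest.fixture(scope="session")
def cloud30():
    return make_fixture(FixtureSpec(kind="random_cloud", n_residues=30,
                                    spacing=3.8, seed=2))


@pytest.fixture(scope="session")
def cloud30_enm(cloud30):
    return ElasticNetworkModel().fit(cloud30)


@pytest.fixture
def rng():
    return np.random.default_rng(20110 + 6)
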