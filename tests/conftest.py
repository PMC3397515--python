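import numpy as np
import pytest

from radamotor import FilamentSpec, build_backbone, make_state_quartet


@pytest.fixture(scope="session")
def quartet():
    """The standard 12-residue backbone-decorated state quartet."""
    return make_state_quartet(FilamentSpec(12, 3.8, 100.0, 2.3, with_backbone=True))


@pytest.fixture(scope="session")
def helix_backbone():
    """Ideal α-helical 10-residue backbone (phi −57°, psi −47°)."""
    return build_backbone([-57.0] * 10, [-47.0] * 10)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_cloud(rng, n, scale=5.0):
    return rng.normal(0.0, scale, (n, 3))
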