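import numpy as np
import pytest

from mskwarp.core import build_template, add_joint_center_doubles
from mskwarp.synthetic import make_fixture_model


@pytest.fixture(scope="session")
def template():
    return build_template()


@pytest.fixture(scope="session")
def template_doubled():
    return add_joint_center_doubles(build_template())


@pytest.fixture(scope="session")
def fixture_model(template_doubled):
    return make_fixture_model(template_doubled)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
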