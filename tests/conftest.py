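import numpy as np
import pytest

import berrycloud as bc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bunch():
    """Default 30-berry synthetic bunch at 600 mm standoff."""
    return bc.generate_bunch(seed=1)


@pytest.fixture(scope="session")
def reference_scan(bunch):
    return bc.render_reference_scan(bunch, density=1.0, seed=2)


@pytest.fixture(scope="session")
def pose(bunch):
    return bc.CameraPose(origin=np.zeros(3), look_at=bunch.centroid)


def sphere_surface_points(rng, center, radius, n):
    """Uniform points on a sphere surface."""
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return np.asarray(center) + radius * d


def random_rotation(rng):
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
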