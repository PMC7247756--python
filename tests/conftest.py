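import numpy as np
import pytest

from cardiofuse.geometry import PlaneGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_geometry():
    return PlaneGeometry(origin=np.zeros(3),
                         row_cosine=np.array([1.0, 0.0, 0.0]),
                         col_cosine=np.array([0.0, 1.0, 0.0]),
                         spacing=np.array([1.0, 1.0]),
                         n_rows=64, n_cols=64)


def random_geometry(rng, spacing=(1.5, 1.2)):
    """Random orthonormal plane pose."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return PlaneGeometry(origin=rng.normal(scale=50.0, size=3),
                         row_cosine=q[:, 0], col_cosine=q[:, 1],
                         spacing=np.asarray(spacing),
                         n_rows=64, n_cols=64)
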