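import numpy as np
import pytest

from knotflux import polymer_mc as pm


@pytest.fixture(scope="session")
def params_6kbp():
    """The standard study conditions: 6-kbp circle, b=10 nm, P=50 nm,
    d=5 nm (N=204 segments)."""
    return pm.ChainParameters()


@pytest.fixture(scope="session")
def params_small():
    """A shorter chain (N=102) for cheaper sampling tests."""
    return pm.ChainParameters(n_bp=3000)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_ring(n, rng, scale=1.0):
    """Smooth random closed curve from a low-order Fourier series."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.zeros((n, 3))
    for k in range(1, 4):
        a = rng.standard_normal(3) / k
        b = rng.standard_normal(3) / k
        pts += np.outer(np.cos(k * t), a) + np.outer(np.sin(k * t), b)
    return pts * scale
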