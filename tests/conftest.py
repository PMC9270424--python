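import numpy as np
import pytest

from rpgdwi import ProtocolConfig, Volume, make_phantom, simulate_acquisition


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_volume(rng):
    """Smooth random 16x16x8 volume, PE along axis 1."""
    data = rng.random((16, 16, 8))
    from scipy.ndimage import gaussian_filter

    return Volume(gaussian_filter(data, 2.0) * 100, (2.0, 2.0, 4.0))


@pytest.fixture(scope="session")
def tiny_cfg():
    """Two-station protocol small enough for fast registration tests."""
    return ProtocolConfig(n_stations=2)


@pytest.fixture(scope="session")
def tiny_truth(tiny_cfg):
    return make_phantom(tiny_cfg, seed=1)


@pytest.fixture(scope="session")
def tiny_acquisition(tiny_truth, tiny_cfg):
    return simulate_acquisition(tiny_truth, tiny_cfg, seed=1)
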