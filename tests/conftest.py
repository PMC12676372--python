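import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def monoexp_noiseless():
    from qmrifit.synthdata import gen_monoexp_volume

    return gen_monoexp_volume(shape=(6, 6, 6), snr=1e9, seed=7)


@pytest.fixture(scope="session")
def gaussian_toy_small():
    from qmrifit.synthdata import gen_gaussian_toy

    return gen_gaussian_toy(n_obs=50, theta_true=1.0, sigma=1.0, seed=9, n_voxels=5)
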