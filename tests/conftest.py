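import numpy as np
import pytest

import wnet


@pytest.fixture(scope="session")
def layout8():
    return wnet.generate_layout(8, seed=1)


@pytest.fixture(scope="session")
def layout16():
    return wnet.generate_layout(16, seed=1)


@pytest.fixture(scope="session")
def layout32():
    return wnet.generate_layout(32, seed=1)


@pytest.fixture(scope="session")
def alpha_pair_recording(layout8):
    """Noiseless unit-coupling alpha pair at lag pi/2: WPLI limit 1."""
    spec = wnet.CouplingSpec(band="alpha", edge_list=((0, 1),),
                             coupling_strength=(1.0,), phase_lag=(np.pi / 2,),
                             noise_sd=0.0)
    return wnet.generate_recording(layout8, [spec], n_epochs=10, fs=256, seed=7)


def random_symmetric(n, rng, low=0.05, high=1.0):
    """Random symmetric zero-diagonal matrix with distinct positive weights."""
    iu, ju = np.triu_indices(n, k=1)
    vals = rng.uniform(low, high, size=len(iu))
    m = np.zeros((n, n))
    m[iu, ju] = vals
    m[ju, iu] = vals
    return m
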