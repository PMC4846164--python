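import numpy as np
import pytest

import rrscan as rr


@pytest.fixture(scope="session")
def toy_model():
    """12-atom, 3-residue elastic-network harmonic model (the standard toy)."""
    return rr.toy_chain_model()


@pytest.fixture(scope="session")
def toy_ensemble(toy_model):
    """15,000 frames sampled from the toy model, superposed to the first frame."""
    ens = rr.sample_frames(toy_model, 15000, seed=2024)
    return rr.superpose(ens, ens.coordinates[0], label="first_frame")


@pytest.fixture(scope="session")
def toy_cov(toy_ensemble):
    return rr.covariance_matrix(toy_ensemble)


@pytest.fixture(scope="session")
def toy_spectrum(toy_model, toy_cov):
    return rr.qh_modes(toy_cov, toy_model.topology, 300.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
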