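import warnings

import numpy as np
import pytest

from mqaprank.synthetic import make_native, perturb_decoys


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        yield


@pytest.fixture(scope="session")
def helix30():
    return make_native(30, fold="helix", seed=11)


@pytest.fixture(scope="session")
def mixed40():
    return make_native(40, fold="mixed", seed=23)


@pytest.fixture(scope="session")
def small_decoy_set(helix30):
    return perturb_decoys(helix30, n=8, sigma_range=(0.0, 5.0), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
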