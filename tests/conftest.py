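import numpy as np
import pytest

import eigendcm as ed

TR = 2.0


@pytest.fixture(scope="session")
def scenario1():
    """Default six-node scenario, seed 1 (shared across the suite)."""
    return ed.default_scenario(1)


@pytest.fixture(scope="session")
def model1(scenario1):
    """Spectral DCM bound to the seed-1 scenario with the correct structure."""
    return ed.SpectralDCM(scenario1.bold.values, TR, n_unstable=3,
                          stable_log_decay=1.0)


@pytest.fixture(scope="session")
def fit1(model1):
    """One full inversion of the seed-1 scenario (reused by many tests)."""
    return model1.fit(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_orthonormal(rng, n):
    """Haar-ish orthonormal matrix with the package sign convention."""
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    for k in range(n):
        i = np.argmax(np.abs(q[:, k]))
        if q[i, k] < 0:
            q[:, k] = -q[:, k]
    return q


def random_stable_symmetric(rng, n, lam_range=(-3.0, -0.2)):
    """Random symmetric negative-definite matrix."""
    q = random_orthonormal(rng, n)
    lam = rng.uniform(*lam_range, size=n)
    return (q * lam) @ q.T
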