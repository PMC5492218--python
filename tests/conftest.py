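import warnings

import numpy as np
import pytest

from pacemg.drift import Session
from pacemg.kernel import KernelParams
from pacemg.synthetic import GeneratorConfig, gen_session

# parameter-range advisories are irrelevant noise in tests that probe edges
warnings.filterwarnings("ignore", message=".*outside the recommended range.*")
warnings.filterwarnings("ignore", message=".*shorter than the reference.*")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def kp():
    return KernelParams(gamma=0.5)


@pytest.fixture(scope="session")
def small_session() -> Session:
    """A 200-sample, 8-class synthetic session (25 per class)."""
    return gen_session(GeneratorConfig(samples_per_class=25, seed=42))


@pytest.fixture(scope="session")
def medium_session() -> Session:
    """A 400-sample, 8-class synthetic session (50 per class)."""
    return gen_session(GeneratorConfig(samples_per_class=50, seed=7))


def two_blobs(n_per: int = 30, sep: float = 12.0, sd: float = 0.5, seed: int = 0):
    """Two well-separated Gaussian blobs in 7 dimensions (sep >= 10 sd)."""
    r = np.random.default_rng(seed)
    a = r.normal(0.0, sd, (n_per, 7))
    b = r.normal(0.0, sd, (n_per, 7))
    b[:, 0] += sep * sd
    X = np.vstack([a, b])
    y = np.array([1] * n_per + [2] * n_per)
    return X, y
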