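import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, scale: float = 1.0, jitter: float = 0.5) -> np.ndarray:
    """A well-conditioned random SPD 3x3 matrix."""
    A = rng.standard_normal((3, 3))
    return scale * (A @ A.T + (1.0 + jitter) * np.eye(3))


@pytest.fixture
def spd_factory(rng):
    def make(scale: float = 1.0):
        return random_spd(rng, scale)

    return make
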