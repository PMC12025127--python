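import numpy as np
import pytest
from scipy.spatial.transform import Rotation


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)


def random_rotation(rng) -> Rotation:
    return Rotation.random(rng=rng)


def random_point(rng, scale=100.0) -> np.ndarray:
    return rng.uniform(-scale, scale, size=3)
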