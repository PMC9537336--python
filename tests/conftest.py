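import numpy as np
import pytest

from wamr.core import FeatureFunction, RecognitionParams, WeightedAMR


@pytest.fixture
def empty_4x4():
    return WeightedAMR(4, 4)


@pytest.fixture
def two_function_2x2():
    """2x2 register holding (0,0) three times and (1,1) once."""
    amr = WeightedAMR(2, 2)
    for _ in range(3):
        amr.register(FeatureFunction.total([0, 0], 2))
    amr.register(FeatureFunction.total([1, 1], 2))
    return amr


@pytest.fixture
def lenient_params():
    return RecognitionParams(iota=0.0, kappa=0.0, xi=0, sigma=0.0)


def random_amr(rng: np.random.Generator, n: int, m: int, density: float = 0.6,
               max_w: int = 9) -> WeightedAMR:
    w = rng.integers(1, max_w + 1, size=(n, m))
    mask = rng.random((n, m)) < density
    return WeightedAMR(n, m, weights=w * mask)


def random_cue(rng: np.random.Generator, n: int, m: int) -> FeatureFunction:
    return FeatureFunction.total(rng.integers(0, m, size=n), m)
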