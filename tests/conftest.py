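import numpy as np
import pytest

from trimlogit import LabeledMatrix
from trimlogit.synthdata import SyntheticSpec, generate


@pytest.fixture(scope="session")
def toy8() -> LabeledMatrix:
    """Small fixed 8x2 problem used across solver tests."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((8, 2))
    y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
    return LabeledMatrix.from_arrays(X, y)


@pytest.fixture(scope="session")
def small_contaminated():
    """n=60, p=20 contaminated dataset plus its ground truth."""
    return generate(SyntheticSpec(n=60, p=20, q=4, effect=2.0, rho=0.2,
                                  epsilon=0.1, seed=42))


@pytest.fixture(scope="session")
def tiny12():
    """n=12, p=3 dataset small enough for exhaustive enumeration."""
    return generate(SyntheticSpec(n=12, p=3, q=2, effect=2.0, rho=0.2,
                                  epsilon=0.1, seed=7))


def make_dataset(n=60, p=20, seed=0, epsilon=0.1, **kw):
    return generate(SyntheticSpec(n=n, p=p, q=kw.pop("q", 4), effect=kw.pop("effect", 2.0),
                                  rho=kw.pop("rho", 0.2), epsilon=epsilon, seed=seed, **kw))
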