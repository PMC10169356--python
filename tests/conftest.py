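import numpy as np
import pytest

from simplexgrad.motifs import MotifLibrary
from simplexgrad.synthetic import generate_dataset


class LinearScorer:
    """f(x) = sum(w * x) + c — the universal closed-form oracle for attribution methods."""

    def __init__(self, w: np.ndarray, c: float = 0.0):
        self.w = np.asarray(w, dtype=float)
        self.c = float(c)

    def input_gradient(self, x, output: str = "logit") -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            return self.w.copy()
        return np.broadcast_to(self.w, x.shape).copy()

    def decision_function(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            return float((self.w * x).sum() + self.c)
        return (self.w * x).sum(axis=(1, 2)) + self.c


@pytest.fixture(scope="session")
def library():
    return MotifLibrary.default()


@pytest.fixture(scope="session")
def tiny_dataset(library):
    """Small but learnable dataset shared by model-level tests."""
    return generate_dataset(n=600, library=library, seed=11)


@pytest.fixture(scope="session")
def easy_dataset(library):
    """Shorter sequences carry denser motif signal, so small models learn fast."""
    return generate_dataset(n=1000, library=library, seed=11, length=100)


@pytest.fixture(scope="session")
def linear_model():
    rng = np.random.default_rng(5)
    return LinearScorer(rng.normal(size=(200, 4)), c=0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
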