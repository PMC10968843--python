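import numpy as np
import pytest
from hypothesis import settings
from sklearn.base import BaseEstimator, ClassifierMixin

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from intervalens import DatasetSpec, generate


class FixedSoftLabels(BaseEstimator, ClassifierMixin):
    """Test double emitting a pre-set per-class score matrix.

    ``fit`` only records the class set; ``predict_proba`` returns the first
    ``len(X)`` rows of the stored matrix, so hand-built interval examples
    can be driven through the full ensemble path.
    """

    def __init__(self, probs=((0.5, 0.5),)):
        self.probs = probs

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        return np.asarray(self.probs, dtype=float)[: len(X)]

    def predict(self, X):
        p = self.predict_proba(X)
        return self.classes_[np.argmax(p, axis=1)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, clearly separable 3-class expression-like dataset."""
    spec = DatasetSpec(
        n_samples=90,
        n_features=60,
        class_probs=(0.5, 0.3, 0.2),
        n_informative=30,
        effect_size=2.0,
        block_size=6,
        seed=7,
    )
    return generate(spec)


def random_interval_bounds(rng, n):
    """n sorted (lower, upper) pairs in [0, 1]."""
    a = rng.random((n, 2))
    a.sort(axis=1)
    return a
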