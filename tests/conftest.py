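import numpy as np
import pytest

from multisol.dataset import ExpressionDataset
from multisol.synthetic_data import generate, preset


def make_dataset(values, labels, positive_class="pos", feature_ids=None,
                 sample_ids=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    if feature_ids is None:
        feature_ids = [f"g{i}" for i in range(m)]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n)]
    return ExpressionDataset(feature_ids, sample_ids, values, labels,
                             positive_class)


@pytest.fixture
def toy_dataset():
    """4 samples x 3 features, labels neg,neg,pos,pos."""
    rng = np.random.default_rng(42)
    return make_dataset(rng.normal(size=(3, 4)),
                        ["neg", "neg", "pos", "pos"])


@pytest.fixture(scope="session")
def easy_dataset():
    """The frozen easy-regime synthetic dataset used across screen tests."""
    return generate(preset("easy", seed=1))


@pytest.fixture(scope="session")
def difficult_dataset():
    return generate(preset("difficult", seed=1))


def random_two_class_dataset(rng, n_features=5, n_per_class=(4, 4)):
    n = sum(n_per_class)
    values = rng.normal(size=(n_features, n))
    labels = ["neg"] * n_per_class[0] + ["pos"] * n_per_class[1]
    return make_dataset(values, labels)
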