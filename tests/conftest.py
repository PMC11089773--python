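import numpy as np
import pytest

from prcmethods import ScoredLabels, fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240513)


@pytest.fixture
def no_ties_small():
    return fixture("no_ties_small")


@pytest.fixture
def all_tied():
    return fixture("all_tied")


@pytest.fixture
def tiny():
    # scores (0.9, 0.8, 0.7, 0.6), labels (1, 1, 0, 1)
    return ScoredLabels([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 1])


def random_instance(rng, n_max=30, tie_prob=0.5):
    """A random small labeled instance, tied or not, with >=1 positive."""
    n = int(rng.integers(2, n_max + 1))
    if rng.random() < tie_prob:
        scores = rng.integers(0, max(2, n // 3), size=n).astype(float)
    else:
        scores = rng.uniform(size=n)
    labels = rng.integers(0, 2, size=n)
    if labels.sum() == 0:
        labels[int(rng.integers(n))] = 1
    return ScoredLabels(scores, labels)
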