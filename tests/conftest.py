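import numpy as np
import pytest

from polyacal import ScoreSample


def planted_blobs(rng, n_per_class: int, sep: float = 2.0):
    """Two isotropic unit-variance 2-D Gaussian classes, centers `sep` apart.

    Returns (features, labels) with label 1 = positive class at the origin.
    """
    pos = rng.normal(0.0, 1.0, (n_per_class, 2))
    neg = rng.normal(0.0, 1.0, (n_per_class, 2)) + [sep, 0.0]
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(n_per_class, int), np.zeros(n_per_class, int)])
    return X, y


@pytest.fixture
def gaussian_samples():
    """Well-separated class score samples: N(0,1) cases vs N(2,1) controls."""
    rng = np.random.default_rng(7)
    return (
        ScoreSample(rng.normal(0, 1, 200), class_label=1),
        ScoreSample(rng.normal(2, 1, 200), class_label=2),
    )
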