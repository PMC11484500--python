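import numpy as np
import pytest

from mirpanel.synthetic import make_plant_fixture


@pytest.fixture(scope="session")
def toy_logistic():
    """Small non-separable 2-feature logistic fixture (overlapping classes)."""
    rng = np.random.default_rng(42)
    n = 20
    X = rng.standard_normal((n, 2))
    eta = 0.8 * X[:, 0] - 0.5 * X[:, 1]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    # overlap check: no single linear direction separates perfectly
    assert 0 < y.sum() < n
    return X, y


@pytest.fixture(scope="session")
def small_plant():
    """Scaled-down cohort fixture: 16 samples x 30 features, 3 planted
    markers, nested subsets of sizes 10/16/22."""
    return make_plant_fixture(seed=7, n_planted=3, n_per_group=4,
                              n_features=30, subset_sizes=(10, 16, 22))
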