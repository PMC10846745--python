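import numpy as np
import pytest

from susie2 import PriorWeights, SERSufficientStats


@pytest.fixture
def rng():
    return np.random.default_rng(20240925)


@pytest.fixture
def toy_suffstats(rng):
    """Sufficient stats from a small standardized regression with signal on x2."""
    n, p = 50, 4
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = 0.8 * X[:, 2] + rng.standard_normal(n)
    y = y - y.mean()
    return (
        SERSufficientStats(xty=X.T @ y, xtx=(X * X).sum(0), n=n, yty=float(y @ y)),
        X,
        y,
    )


@pytest.fixture
def uniform4():
    return PriorWeights.uniform(4)
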