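import numpy as np
import pytest

from lgpois import CountDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def small_poisson_dataset(rng):
    """N=20, K=2 (intercept + slope), moderate counts."""
    x = rng.standard_normal(20)
    X = np.column_stack([np.ones(20), x])
    lam = np.exp(0.5 + 0.8 * x)
    y = rng.poisson(lam)
    return CountDataset(y=y, X=X)


def make_dataset(rng, n=50, beta=(0.5, 0.8), sigma2=1.0, offset=None):
    from lgpois import gen_odpoisson

    k = len(beta) - 1
    x = rng.standard_normal((n, k))
    X = np.column_stack([np.ones(n), x])
    lam = np.exp(X @ np.asarray(beta))
    z = np.ones(n) if offset is None else np.asarray(offset, dtype=float)
    y = gen_odpoisson(lam * z, sigma2, rng)
    return CountDataset(y=y, X=X, z=z)
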