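import numpy as np
import pytest

from survemvs.data import SurvivalDataset


def make_dataset(n=50, p=3, q=0, seed=0, alpha=1.0, beta=None, censor=0.4,
                 standardize=True):
    """Small Weibull dataset with known generative parameters."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Z = rng.standard_normal((n, q)) if q else None
    beta = np.zeros(p) if beta is None else np.asarray(beta, dtype=float)
    eta = X @ beta
    lam = np.exp(-eta)
    t = (rng.exponential(size=n) / lam) ** (1.0 / alpha)
    if censor > 0:
        c = rng.uniform(0, np.quantile(t, 1.0 - censor) * 2.5, size=n)
        T = np.minimum(t, c)
        d = (t <= c).astype(float)
    else:
        T, d = t, np.ones(n)
    return SurvivalDataset(T, d, X, Z=Z, standardize=standardize)


@pytest.fixture
def small_data():
    return make_dataset(n=50, p=3, seed=1)
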