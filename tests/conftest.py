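import numpy as np
import pytest

from survscreen import SurvivalData


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_censored_data(rng, n=60, p=5, censor_frac=0.3):
    """Small random survival sample with roughly the requested censoring."""
    X = rng.standard_normal((n, p))
    T = rng.exponential(size=n)
    C = rng.exponential(scale=(1 - censor_frac) / max(censor_frac, 1e-6), size=n)
    V = np.minimum(T, C)
    delta = (T <= C).astype(int)
    if delta.sum() == 0:
        delta[0] = 1
    return SurvivalData(X, V + 1e-9, delta)


@pytest.fixture
def censored_data(rng):
    return random_censored_data(rng)
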