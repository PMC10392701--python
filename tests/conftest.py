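import numpy as np
import pytest

from wqs2i import MixtureData, quantize_columns


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_data(rng):
    """n=300, c=4 identity-link dataset with a known positive mixture."""
    n, c = 300, 4
    X = rng.standard_normal((n, c))
    Q = quantize_columns(X, 4)
    y = 0.8 * (0.6 * Q[:, 0] + 0.4 * Q[:, 1]) + rng.normal(0, 0.5, n)
    return MixtureData(y=y, Q=Q, q=4)


@pytest.fixture
def logit_data(rng):
    """n=600, c=3 binary-outcome dataset with a positive index effect."""
    n, c = 600, 3
    X = rng.standard_normal((n, c))
    Q = quantize_columns(X, 4)
    eta = -1.0 + 0.5 * (0.7 * Q[:, 0] + 0.3 * Q[:, 1])
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return MixtureData(y=y, Q=Q, q=4, link="logit")
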