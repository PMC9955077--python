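import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_instance(rng, n_max=40, l_choices=(3, 4, 5), k_max=3):
    """A small random detection instance (Gaussian measurement, Gaussian
    template) for oracle-equivalence checks."""
    l = int(rng.choice(l_choices))
    n = int(rng.integers(l * max(k_max, 1), n_max + 1))
    k = int(rng.integers(0, min(k_max, n // l) + 1))
    y = rng.normal(size=n)
    x = rng.normal(size=l)
    if np.dot(x, x) == 0:  # vanishingly unlikely; keep the invariant anyway
        x[0] = 1.0
    return y, x, k
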