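import numpy as np
import pytest

from isingfold.partition import OrderParameterSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_energy(rng, n, density=0.5, scale=2.0):
    """Random attractive contact-energy matrix, (N+1, N+1) kcal/mol."""
    e = np.zeros((n + 1, n + 1))
    for i in range(1, n - 2):
        for j in range(i + 3, n + 1):
            if rng.random() < density:
                e[i, j] = e[j, i] = -rng.random() * scale
    return e


def random_s(rng, n):
    return np.concatenate([[0.0], -rng.random(n) * 3.0 - 0.5])


def random_spec(rng, n, ndim):
    if ndim == 1:
        return OrderParameterSpec.single(n)
    set1 = sorted(rng.choice(np.arange(1, n + 1), size=n // 2,
                             replace=False).tolist())
    return OrderParameterSpec.split(n, set1)


def random_linker(rng, n, taken=()):
    while True:
        u = int(rng.integers(1, n - 3))
        v = int(rng.integers(u + 3, n + 1))
        if (u, v) not in taken:
            return (u, v)
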