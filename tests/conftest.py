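import numpy as np
import pytest

from sparsefa import DataSummary, generate_dataset, make_preset


@pytest.fixture(scope="session")
def sim1():
    return make_preset("sim1")


@pytest.fixture(scope="session")
def sim2_null():
    return make_preset("sim2-null")


@pytest.fixture(scope="session")
def sim1_data(sim1):
    """One seeded single-group replicate at N = 500."""
    X, _ = generate_dataset(sim1, 500, np.random.default_rng(20240101))
    return DataSummary.from_raw(X)


@pytest.fixture(scope="session")
def sim2_data(sim2_null):
    """One seeded two-group replicate at N = 600."""
    X, labels = generate_dataset(sim2_null, 600, np.random.default_rng(20240102))
    return DataSummary.from_raw(X, labels)


def fd_gradient(fun, x, h=1e-6):
    """Central finite differences of a scalar function."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for k in range(x.size):
        e = np.zeros_like(x)
        e[k] = h * max(1.0, abs(x[k]))
        g[k] = (fun(x + e) - fun(x - e)) / (2 * e[k])
    return g
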