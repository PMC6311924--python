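import numpy as np
import pytest

from bermix import CountData, ModelParameters


def make_data(counts, labels, prefix="s"):
    counts = np.asarray(counts)
    return CountData(
        sample_ids=[f"{prefix}{i}" for i in range(counts.shape[0])],
        taxon_ids=[f"t{j}" for j in range(counts.shape[1])],
        counts=counts,
        labels=np.asarray(labels),
    )


def random_instance(rng, n=6, k=3, L=2, gamma=0.5, max_count=8):
    """A small random (data, params, Z) triple with everything strictly positive."""
    counts = rng.integers(0, max_count, size=(n, k))
    counts[:, 0] += 1  # keep row totals positive
    data = make_data(counts, rng.integers(0, 2, size=n))
    params = ModelParameters(
        phi=rng.dirichlet(np.ones(L)),
        rho=rng.uniform(0.05, 0.95, size=L),
        P=rng.dirichlet(np.ones(k), size=L),
        gamma=gamma,
    )
    Z = rng.dirichlet(np.ones(L), size=n)
    return data, params, Z


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_data():
    """4 samples x 3 taxa, mixed labels."""
    return make_data(
        [[3, 1, 0], [0, 4, 1], [2, 2, 2], [5, 0, 1]],
        [1, 0, 1, 0],
    )
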