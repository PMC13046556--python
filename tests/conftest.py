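import numpy as np
import pandas as pd
import pytest

from cfosnet import ActivationMatrix, default_config, simulate_dataset


@pytest.fixture(scope="session")
def study_matrix():
    """One default synthetic study draw (6/6/9 animals, 4 regions)."""
    return simulate_dataset(default_config(), seed=20_260_101)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, groups, regions=None, ids=None):
    """Build an ActivationMatrix from a plain array and group labels."""
    values = np.asarray(values, dtype=float)
    regions = regions or [f"R{i}" for i in range(values.shape[1])]
    ids = ids or [f"i{k}" for k in range(values.shape[0])]
    data = pd.DataFrame(values, index=ids, columns=regions)
    return ActivationMatrix(data, pd.Series(list(groups), index=ids, name="group"))


@pytest.fixture()
def two_cluster_matrix(rng):
    """Two tight, well-separated clusters of 5 individuals each."""
    a = rng.normal(1.0, 0.01, size=(5, 4))
    b = rng.normal(6.0, 0.01, size=(5, 4))
    return make_matrix(np.vstack([a, b]), ["A"] * 5 + ["B"] * 5)
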