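import numpy as np
import pytest

from selenergy import Composition, CountTable, GroupLabels


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table(rng):
    counts = rng.integers(0, 60, size=(20, 8))
    counts[:, 0] += 1  # guarantee nonzero rows
    return CountTable(counts,
                      [f"s{i}" for i in range(20)],
                      [f"T{j}" for j in range(8)])


@pytest.fixture
def binary_labels():
    return GroupLabels(np.array(["a"] * 10 + ["b"] * 10))


def make_composition(values, names=None):
    values = np.asarray(values, dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    names = names or [f"t{j + 1}" for j in range(values.shape[1])]
    return Composition(values, names,
                       strictly_positive=bool(np.all(values > 0)))


@pytest.fixture
def positive_composition(rng):
    vals = rng.dirichlet(np.full(6, 2.0), size=16)
    return Composition(vals / vals.sum(1, keepdims=True),
                       [f"t{j + 1}" for j in range(6)], strictly_positive=True)
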