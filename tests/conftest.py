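import numpy as np
import pytest
from hypothesis import settings

from medsup import LabeledTable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_nb_table() -> LabeledTable:
    """One attribute: class A at (0, 1, 2), class B at (4, 5, 6).

    Hand-computable Gaussian fit: priors (0.5, 0.5), means (1, 5),
    unbiased sds (1, 1).
    """
    values = np.array([[0.0], [1.0], [2.0], [4.0], [5.0], [6.0]])
    labels = ["A", "A", "A", "B", "B", "B"]
    return LabeledTable(["x"], values, labels)


@pytest.fixture
def separable_table() -> LabeledTable:
    """1-D linearly separable two-cluster data."""
    rng = np.random.default_rng(7)
    a = rng.uniform(0.0, 3.0, size=20)
    b = rng.uniform(10.0, 13.0, size=20)
    values = np.concatenate([a, b])[:, None]
    labels = ["A"] * 20 + ["B"] * 20
    return LabeledTable(["x"], values, labels)


def random_imbalanced_table(rng: np.random.Generator) -> LabeledTable:
    """A small random two-class table, possibly with negative values."""
    n1 = int(rng.integers(2, 25))
    n2 = int(rng.integers(1, n1 + 1))
    p = int(rng.integers(1, 6))
    values = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 4), size=(n1 + n2, p))
    labels = ["maj"] * n1 + ["min"] * n2
    perm = rng.permutation(n1 + n2)
    return LabeledTable(
        [f"f{j}" for j in range(p)], values[perm], np.asarray(labels, dtype=object)[perm]
    )
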