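import numpy as np
import pytest

import nbhdclass as nc
from nbhdclass import Digraph, from_edge_list


@pytest.fixture(scope="session")
def experiment():
    """Seeded scaled-down experiment: ER digraph (n=300, p=0.01), 8
    stimulus classes x 100 repeats with the generator defaults."""
    g, design, schedule, dyn = nc.generate_dataset(
        n=300, p=0.01, num_classes=8, repeats=100, seed=42
    )
    table = nc.parameter_table(g, ["size", "asg"])
    return g, design, schedule, dyn, table


@pytest.fixture
def t3() -> Digraph:
    """Transitive triangle: the directed 3-clique 0 -> 1 -> 2, 0 -> 2."""
    return from_edge_list([(0, 1), (0, 2), (1, 2)])


@pytest.fixture
def c3() -> Digraph:
    """Cyclic triangle 0 -> 1 -> 2 -> 0 (no linear order)."""
    return from_edge_list([(0, 1), (1, 2), (2, 0)])


@pytest.fixture
def k3() -> Digraph:
    """Complete reciprocal digraph on 3 vertices (all six arcs)."""
    return from_edge_list(
        [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
    )


@pytest.fixture
def path3() -> Digraph:
    """Directed path 0 -> 1 -> 2."""
    return from_edge_list([(0, 1), (1, 2)])


def random_digraph(n: int, p: float, rng: np.random.Generator) -> Digraph:
    import scipy.sparse as sp

    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    return Digraph(sp.csr_matrix(mask))


def complete_reciprocal(n: int) -> Digraph:
    return from_edge_list(
        [(i, j) for i in range(n) for j in range(n) if i != j]
    )
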