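import networkx as nx
import numpy as np
import pytest

from pirank.data_io import OntologyDAG
from pirank.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def chain_dag():
    """r -> a -> c."""
    g = nx.DiGraph()
    g.add_edge("r", "a")
    g.add_edge("a", "c")
    return OntologyDAG(g)


@pytest.fixture(scope="session")
def sibling_dag():
    """Root r with children a, b."""
    g = nx.DiGraph()
    g.add_edge("r", "a")
    g.add_edge("r", "b")
    return OntologyDAG(g)


@pytest.fixture(scope="session")
def diamond_dag():
    """r -> {a, b} -> d."""
    g = nx.DiGraph()
    g.add_edges_from([("r", "a"), ("r", "b"), ("a", "d"), ("b", "d")])
    return OntologyDAG(g)


SMALL_CONFIG = SyntheticConfig(
    n_families=10, members_per_family=6, dag_depth=2, dag_branching=(4, 2),
    n_disease_clusters=4, seed=7,
)


@pytest.fixture(scope="session")
def small_dataset():
    """60 piRNAs in 10 families, 8 diseases in 4 clusters: fast but solvable."""
    return generate_dataset(SMALL_CONFIG)


def make_separable_groups(rng, n_groups=10, n_candidates=12, n_pos=3, dim=4):
    """Query groups whose positives score uniformly higher on every feature."""
    groups = []
    for g in range(n_groups):
        y = np.zeros(n_candidates, dtype=np.int8)
        y[rng.choice(n_candidates, size=n_pos, replace=False)] = 1
        X = rng.uniform(0.0, 0.3, size=(n_candidates, dim))
        X[y == 1] = rng.uniform(0.6, 1.0, size=(n_pos, dim))
        groups.append((f"q{g}", X, y))
    return groups


@pytest.fixture()
def separable_groups():
    return make_separable_groups(np.random.default_rng(42))
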