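import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hybridbn import (DiscreteBayesNet, DirectedAcyclicStructure, Variable)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# shared structures and oracle helpers
# ---------------------------------------------------------------------------

def binary_vars(*names: str) -> list[Variable]:
    return [Variable(n, 2) for n in names]


def enumerate_all_dags(variables):
    """Brute-force oracle: every DAG over the variables, by enumerating all
    binary off-diagonal adjacency matrices and keeping the acyclic ones."""
    n = len(variables)
    slots = [(i, j) for i in range(n) for j in range(n) if i != j]
    dags = []
    for bits in itertools.product((0, 1), repeat=len(slots)):
        adj = np.zeros((n, n), dtype=np.int8)
        for (i, j), b in zip(slots, bits):
            adj[i, j] = b
        if _is_acyclic(adj):
            dags.append(DirectedAcyclicStructure.from_adjacency(
                variables, adj, validate=False))
    return dags


def _is_acyclic(adj: np.ndarray) -> bool:
    """Kahn's algorithm on a dense matrix (oracle-side acyclicity check)."""
    adj = adj.copy()
    n = adj.shape[0]
    alive = np.ones(n, dtype=bool)
    while alive.any():
        indeg = adj[alive][:, alive].sum(axis=0)
        if (indeg > 0).all():
            return False
        nodes = np.nonzero(alive)[0]
        alive[nodes[np.nonzero(indeg == 0)[0]]] = False
        adj[~alive] = 0
        adj[:, ~alive] = 0
    return True


@pytest.fixture
def fig1_structure():
    """The 4-node toy structure with arcs A->B, B->C, B->D."""
    return DirectedAcyclicStructure(binary_vars("A", "B", "C", "D"),
                                    [("A", "B"), ("B", "C"), ("B", "D")])


@pytest.fixture
def chain_bn():
    """Strongly coupled 3-node chain A -> B -> C."""
    variables = binary_vars("A", "B", "C")
    structure = DirectedAcyclicStructure(variables, [("A", "B"), ("B", "C")])
    cpts = {
        "A": np.array([[0.4, 0.6]]),
        "B": np.array([[0.9, 0.1], [0.15, 0.85]]),
        "C": np.array([[0.85, 0.15], [0.1, 0.9]]),
    }
    return DiscreteBayesNet(structure, cpts)


@pytest.fixture
def collider_bn():
    """Collider X -> W <- Y with independent binary causes."""
    variables = binary_vars("X", "Y", "W")
    structure = DirectedAcyclicStructure(variables, [("X", "W"), ("Y", "W")])
    cpts = {
        "X": np.array([[0.5, 0.5]]),
        "Y": np.array([[0.5, 0.5]]),
        # noisy OR: each parent raises P(W=1), so both legs show marginal
        # dependence while X and Y stay marginally independent
        "W": np.array([[0.9, 0.1], [0.3, 0.7], [0.25, 0.75], [0.05, 0.95]]),
    }
    return DiscreteBayesNet(structure, cpts)


def random_dag(variables, rng, p_edge=0.4) -> DirectedAcyclicStructure:
    """A random DAG drawn by ordering the nodes and keeping forward edges."""
    n = len(variables)
    order = rng.permutation(n)
    adj = np.zeros((n, n), dtype=np.int8)
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p_edge:
                adj[order[a], order[b]] = 1
    return DirectedAcyclicStructure.from_adjacency(variables, adj)
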