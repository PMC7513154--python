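"""Core data model: variables, structures, discrete Bayesian networks, datasets.

A Bayesian network is a pair ``(G, rho)``: a directed acyclic graph over a
set of discrete variables plus, for every variable, a conditional probability
table (CPT) giving the distribution of the variable for each joint
configuration of its parents.  The joint distribution factorizes as the
product of the per-node conditionals.

Conventions used throughout the package:

* Variables are identified by name; the *variable order* is the declaration
  order, and node-pair indices follow :func:`enumerate_node_pairs` on that
  order.
* CPT rows are indexed by a mixed-radix encoding of the parent states with
  the first-listed parent (in variable order) most significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Variable",
    "EdgeState",
    "DirectedAcyclicStructure",
    "PartialStructure",
    "DiscreteBayesNet",
    "DiscreteDataset",
    "enumerate_node_pairs",
    "count_dags",
    "joint_probability",
    "forward_sample",
]

PROB_ATOL = 1e-9


@dataclass(frozen=True)
class Variable:
    """A discrete random variable with states coded ``0..arity-1``."""

    name: str
    arity: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variable name must be non-empty")
        if self.arity < 2:
            raise ValueError(f"variable {self.name!r}: arity must be >= 2, got {self.arity}")


class EdgeState(Enum):
    """State of the edge on an *ordered* node pair (X, Y)."""

    FORWARD = "->"  # X -> Y
    REVERSE = "<-"  # Y -> X
    ABSENT = "absent"

    def flipped(self) -> "EdgeState":
        if self is EdgeState.FORWARD:
            return EdgeState.REVERSE
        if self is EdgeState.REVERSE:
            return EdgeState.FORWARD
        return EdgeState.ABSENT


def enumerate_node_pairs(n: int) -> list[tuple[int, int]]:
    """All n(n-1)/2 unordered pairs of node indices, in row-major order.

    For four nodes A, B, C, D the order is (A,B), (A,C), (A,D), (B,C),
    (B,D), (C,D); pair ``j`` in this list is the j-th node pair.
    """
    if n < 1:
        raise ValueError(f"need at least one node, got n={n}")
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def count_dags(n: int) -> int:
    """Number of labelled DAGs on ``n`` nodes (Robinson's recurrence).

    f(1) = 1 and
    f(n) = sum_{i=1..n} (-1)^{i+1} C(n, i) 2^{i(n-i)} f(n-i).
    """
    if n < 1:
        raise ValueError(f"need at least one node, got n={n}")
    f = [1, 1]  # f[0] = 1 makes the recurrence uniform
    for m in range(2, n + 1):
        total = 0
        for i in range(1, m + 1):
            total += (-1) ** (i + 1) * math.comb(m, i) * 2 ** (i * (m - i)) * f[m - i]
        f.append(total)
    return f[n]


def _check_unique_names(variables: Sequence[Variable]) -> None:
    names = [v.name for v in variables]
    if len(set(names)) != len(names):
        raise ValueError("variable names must be unique")


class DirectedAcyclicStructure:
    """A DAG over named discrete variables.

    Arcs are ordered (parent, child) name pairs.  At most one arc may exist
    per unordered pair and the arc set must admit a topological order.
    """

    def __init__(self, variables: Sequence[Variable], arcs: Iterable[tuple[str, str]] = (),
                 validate: bool = True):
        self.variables: tuple[Variable, ...] = tuple(variables)
        self.arcs: set[tuple[str, str]] = set(arcs)
        self._index = {v.name: i for i, v in enumerate(self.variables)}
        if validate:
            self._validate()

    def _validate(self) -> None:
        _check_unique_names(self.variables)
        for p, c in self.arcs:
            if p not in self._index or c not in self._index:
                raise ValueError(f"arc ({p}, {c}) references unknown variable")
            if p == c:
                raise ValueError(f"self-arc on {p!r} not allowed")
            if (c, p) in self.arcs:
                raise ValueError(f"both orientations present for pair ({p}, {c})")
        self.topological_order()  # raises on cycles

    # -- queries ---------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def index(self, name: str) -> int:
        return self._index[name]

    def arity(self, name: str) -> int:
        return self.variables[self._index[name]].arity

    def parents(self, name: str) -> list[str]:
        """Parents of ``name`` in variable order."""
        return [v.name for v in self.variables if (v.name, name) in self.arcs]

    def children(self, name: str) -> list[str]:
        return [v.name for v in self.variables if (name, v.name) in self.arcs]

    def pair_state(self, x: str, y: str) -> EdgeState:
        if (x, y) in self.arcs:
            return EdgeState.FORWARD
        if (y, x) in self.arcs:
            return EdgeState.REVERSE
        return EdgeState.ABSENT

    def topological_order(self) -> list[str]:
        """Kahn's algorithm, breaking ties by variable index so the order
        (and anything consuming randomness along it) is reproducible."""
        import heapq

        n = len(self.variables)
        indeg = [0] * n
        children: list[list[int]] = [[] for _ in range(n)]
        for p, c in self.arcs:
            children[self._index[p]].append(self._index[c])
            indeg[self._index[c]] += 1
        heap = [i for i in range(n) if indeg[i] == 0]
        heapq.heapify(heap)
        order: list[str] = []
        while heap:
            i = heapq.heappop(heap)
            order.append(self.variables[i].name)
            for j in sorted(children[i]):
                indeg[j] -= 1
                if indeg[j] == 0:
                    heapq.heappush(heap, j)
        if len(order) != n:
            raise ValueError("arc set contains a directed cycle")
        return order

    def adjacency(self) -> np.ndarray:
        """Binary adjacency matrix in variable order (adj[i, j] = 1 iff i -> j)."""
        n = len(self.variables)
        adj = np.zeros((n, n), dtype=np.int8)
        for p, c in self.arcs:
            adj[self._index[p], self._index[c]] = 1
        return adj

    @classmethod
    def from_adjacency(cls, variables: Sequence[Variable], adj: np.ndarray,
                       validate: bool = True) -> "DirectedAcyclicStructure":
        names = [v.name for v in variables]
        arcs = [(names[i], names[j]) for i, j in zip(*np.nonzero(adj))]
        return cls(variables, arcs, validate=validate)

    def copy(self) -> "DirectedAcyclicStructure":
        return DirectedAcyclicStructure(self.variables, set(self.arcs), validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedAcyclicStructure):
            return NotImplemented
        return self.variables == other.variables and self.arcs == other.arcs

    def __repr__(self) -> str:
        return f"DirectedAcyclicStructure({len(self.variables)} nodes, {len(self.arcs)} arcs)"


class PartialStructure:
    """A mixed graph with directed arcs and undirected edges.

    This is the intermediate object of constraint-based learning: the
    skeleton carries undirected edges, v-structure orientation turns some of
    them into arcs, and knowledge rules edit both sets.  Undirected edges
    are stored with endpoints in variable order.
    """

    def __init__(self, variables: Sequence[Variable],
                 directed_arcs: Iterable[tuple[str, str]] = (),
                 undirected_edges: Iterable[tuple[str, str]] = ()):
        self.variables: tuple[Variable, ...] = tuple(variables)
        self._index = {v.name: i for i, v in enumerate(self.variables)}
        _check_unique_names(self.variables)
        self.directed_arcs: set[tuple[str, str]] = set(directed_arcs)
        self.undirected_edges: set[tuple[str, str]] = {
            self.canonical_pair(x, y) for x, y in undirected_edges
        }
        for x, y in list(self.directed_arcs) + list(self.undirected_edges):
            if x == y:
                raise ValueError(f"self-edge on {x!r} not allowed")
            if x not in self._index or y not in self._index:
                raise ValueError(f"edge ({x}, {y}) references unknown variable")
        for p, c in self.directed_arcs:
            if self.canonical_pair(p, c) in self.undirected_edges:
                raise ValueError(f"pair ({p}, {c}) is both directed and undirected")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def canonical_pair(self, x: str, y: str) -> tuple[str, str]:
        return (x, y) if self._index[x] < self._index[y] else (y, x)

    def has_undirected(self, x: str, y: str) -> bool:
        return self.canonical_pair(x, y) in self.undirected_edges

    def is_adjacent(self, x: str, y: str) -> bool:
        return (self.has_undirected(x, y) or (x, y) in self.directed_arcs
                or (y, x) in self.directed_arcs)

    def neighbors(self, x: str) -> list[str]:
        """All nodes adjacent to ``x`` (by arc in either direction or edge)."""
        return [v.name for v in self.variables if v.name != x and self.is_adjacent(x, v.name)]

    def copy(self) -> "PartialStructure":
        return PartialStructure(self.variables, set(self.directed_arcs),
                                set(self.undirected_edges))

    def directed_would_cycle(self, extra_arc: tuple[str, str],
                             removed: frozenset[tuple[str, str]] = frozenset()) -> bool:
        """Would the directed part contain a cycle after adding ``extra_arc``?"""
        arcs = (self.directed_arcs - removed) | {extra_arc}
        try:
            DirectedAcyclicStructure(self.variables, arcs)
        except ValueError:
            return True
        return False

    def __repr__(self) -> str:
        return (f"PartialStructure({len(self.variables)} nodes, "
                f"{len(self.directed_arcs)} arcs, {len(self.undirected_edges)} edges)")


@dataclass
class DiscreteDataset:
    """N records of integer state codes over an ordered variable list."""

    variables: tuple[Variable, ...]
    records: np.ndarray  # shape (N, n), integer codes

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        _check_unique_names(self.variables)
        self.records = np.asarray(self.records, dtype=np.int64)
        if self.records.ndim != 2 or self.records.shape[1] != len(self.variables):
            raise ValueError("records must be an (N, n_variables) array")
        if self.records.shape[0] < 1:
            raise ValueError("dataset must contain at least one record")
        for i, v in enumerate(self.variables):
            col = self.records[:, i]
            if col.min() < 0 or col.max() >= v.arity:
                raise ValueError(f"values of {v.name!r} outside 0..{v.arity - 1}")

    @property
    def n_records(self) -> int:
        return int(self.records.shape[0])

    def column(self, name: str) -> np.ndarray:
        idx = [v.name for v in self.variables].index(name)
        return self.records[:, idx]


def _parent_row_index(states: np.ndarray, arities: Sequence[int]) -> np.ndarray:
    """Mixed-radix index of parent configurations; first parent most significant."""
    if len(arities) == 0:
        return np.zeros(states.shape[0] if states.ndim > 1 else 1, dtype=np.int64)
    idx = np.zeros(states.shape[0], dtype=np.int64)
    for t, r in enumerate(arities):
        idx = idx * r + states[:, t]
    return idx


class DiscreteBayesNet:
    """A DAG plus one CPT per variable.

    ``cpts[name]`` is an array of shape ``(q, r)`` where ``q`` is the product
    of the parent arities (1 for root nodes) and ``r`` the variable's arity.
    Row order follows the mixed-radix convention of the module docstring.
    """

    def __init__(self, structure: DirectedAcyclicStructure,
                 cpts: Mapping[str, np.ndarray]):
        self.structure = structure
        self.cpts: dict[str, np.ndarray] = {}
        for v in structure.variables:
            if v.name not in cpts:
                raise ValueError(f"missing CPT for variable {v.name!r}")
            table = np.asarray(cpts[v.name], dtype=float)
            q = int(np.prod([structure.arity(p) for p in structure.parents(v.name)],
                            dtype=object)) if structure.parents(v.name) else 1
            if table.shape != (q, v.arity):
                raise ValueError(
                    f"CPT for {v.name!r} must have shape ({q}, {v.arity}), got {table.shape}")
            if (table < -PROB_ATOL).any():
                raise ValueError(f"CPT for {v.name!r} has negative entries")
            sums = table.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=PROB_ATOL, rtol=0.0):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"CPT row {bad} of {v.name!r} sums to {sums[bad]:.12g}, expected 1")
            self.cpts[v.name] = table

    @property
    def variables(self) -> tuple[Variable, ...]:
        return self.structure.variables

    def parent_row(self, name: str, assignment: Mapping[str, int]) -> int:
        parents = self.structure.parents(name)
        idx = 0
        for p in parents:
            idx = idx * self.structure.arity(p) + assignment[p]
        return idx


def joint_probability(bn: DiscreteBayesNet, assignment: Mapping[str, int]) -> float:
    """Joint probability of a full assignment, by the chain-rule factorization."""
    prob = 1.0
    for v in bn.variables:
        if v.name not in assignment:
            raise ValueError(f"assignment is missing variable {v.name!r}")
        state = assignment[v.name]
        if not 0 <= state < v.arity:
            raise ValueError(f"state {state} out of range for {v.name!r}")
        row = bn.parent_row(v.name, assignment)
        prob *= float(bn.cpts[v.name][row, state])
    return prob


def forward_sample(bn: DiscreteBayesNet, n_samples: int,
                   seed: int | np.random.Generator) -> DiscreteDataset:
    """Ancestral sampling: each node drawn from its CPT row given sampled parents.

    Deterministic for a fixed integer seed.  Nodes are sampled in topological
    order; within a node, all records are drawn at once with inverse-CDF
    sampling.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    structure = bn.structure
    names = structure.names
    col = {name: i for i, name in enumerate(names)}
    records = np.zeros((n_samples, len(names)), dtype=np.int64)
    for name in structure.topological_order():
        parents = structure.parents(name)
        table = bn.cpts[name]
        if parents:
            pstates = records[:, [col[p] for p in parents]]
            rows = _parent_row_index(pstates, [structure.arity(p) for p in parents])
        else:
            rows = np.zeros(n_samples, dtype=np.int64)
        cdf = np.cumsum(table, axis=1)
        u = rng.random(n_samples)
        drawn = (u[:, None] > cdf[rows]).sum(axis=1)
        records[:, col[name]] = np.minimum(drawn, table.shape[1] - 1)
    return DiscreteDataset(structure.variables, records)
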