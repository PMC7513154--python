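"""Binary particle swarm optimization over DAG space.

Each particle's position is a binary adjacency matrix over the ordered node
pairs; a sigmoid-thresholded velocity update drives the bits, and every
position is repaired to acyclicity after each move.  The swarm is seeded
half from random orientations of the stage-1 structure and half from sparse
random digraphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import DirectedAcyclicStructure, PartialStructure

__all__ = ["SwarmParams", "complete_orientation", "repair_acyclic",
           "bpso_search", "hill_climb"]


@dataclass(frozen=True)
class SwarmParams:
    """BPSO hyperparameters.

    ``v_max`` bounds the velocity entrywise and thereby floors the per-bit
    flip probability at ``sigmoid(-v_max)``; 6 keeps that floor at 0.25%,
    small enough for the swarm to converge on networks with tens of node
    pairs while still escaping local optima.
    """

    n_particles: int = 30
    n_iterations: int = 200
    inertia: float = 0.8
    cognitive: float = 2.0
    social: float = 2.0
    v_max: float = 6.0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        for name in ("inertia", "cognitive", "social", "v_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def complete_orientation(h: PartialStructure,
                         rng: np.random.Generator) -> DirectedAcyclicStructure:
    """Extend a partial structure to a DAG by orienting undirected edges.

    Edges are processed in node-pair order; each gets a uniformly random
    direction, falling back to the opposite direction if the choice closes a
    directed cycle, and dropping the edge if both directions do.
    """
    names = h.names
    index = {n: i for i, n in enumerate(names)}
    arcs = set(h.directed_arcs)
    edges = sorted(h.undirected_edges, key=lambda e: (index[e[0]], index[e[1]]))
    for (x, y) in edges:
        first = (x, y) if rng.random() < 0.5 else (y, x)
        second = (first[1], first[0])
        for cand in (first, second):
            try:
                DirectedAcyclicStructure(h.variables, arcs | {cand})
            except ValueError:
                continue
            arcs.add(cand)
            break
    return DirectedAcyclicStructure(h.variables, arcs, validate=False)


def _find_cycle(adj: np.ndarray) -> list[tuple[int, int]] | None:
    """A directed cycle as a list of arcs, or None (iterative DFS)."""
    n = adj.shape[0]
    color = np.zeros(n, dtype=np.int8)  # 0 white, 1 on stack, 2 done
    parent_arc: dict[int, int] = {}
    for start in range(n):
        if color[start]:
            continue
        stack = [(start, iter(np.nonzero(adj[start])[0]))]
        color[start] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                nxt = int(nxt)
                if color[nxt] == 0:
                    color[nxt] = 1
                    parent_arc[nxt] = node
                    stack.append((nxt, iter(np.nonzero(adj[nxt])[0])))
                    advanced = True
                    break
                if color[nxt] == 1:
                    # found a back arc node -> nxt; unwind the stack
                    cycle = [(node, nxt)]
                    cur = node
                    while cur != nxt:
                        prev = parent_arc[cur]
                        cycle.append((prev, cur))
                        cur = prev
                    return cycle
            if not advanced:
                color[node] = 2
                stack.pop()
    return None


def repair_acyclic(position: np.ndarray) -> np.ndarray:
    """Remove arcs until the adjacency matrix is acyclic.

    While a directed cycle exists, the cycle arc with the largest ordered
    row-major pair index is removed.  Idempotent on acyclic input; the
    diagonal is always cleared.
    """
    adj = np.array(position, dtype=np.int8, copy=True)
    np.fill_diagonal(adj, 0)
    n = adj.shape[0]
    while True:
        cycle = _find_cycle(adj)
        if cycle is None:
            return adj
        i, j = max(cycle, key=lambda arc: arc[0] * n + arc[1])
        adj[i, j] = 0


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def bpso_search(score_fn: Callable[[DirectedAcyclicStructure], float],
                seed_structure: PartialStructure,
                params: SwarmParams,
                rng: np.random.Generator,
                ) -> tuple[DirectedAcyclicStructure, float, list[float]]:
    """Maximize ``score_fn`` over DAGs by binary PSO.

    Half the swarm starts from independent random orientations of
    ``seed_structure``, the other half from sparse random digraphs; all
    positions are repaired to acyclicity before scoring.  Returns the global
    best structure, its score, and the per-iteration best-score trace
    (entry 0 is the best initial particle; the trace is non-decreasing).

    ``score_fn`` may expose a ``score_adjacency(adj)`` method (as
    :class:`hybridbn.scoring.StructureScorer` does) to skip structure-object
    construction in the inner loop.
    """
    variables = seed_structure.variables
    n = len(variables)
    P = params.n_particles
    score_adj = getattr(score_fn, "score_adjacency", None)
    if score_adj is None:
        def score_adj(adj: np.ndarray) -> float:  # type: ignore[misc]
            return score_fn(DirectedAcyclicStructure.from_adjacency(
                variables, adj, validate=False))

    positions = np.zeros((P, n, n), dtype=np.int8)
    n_seeded = P // 2
    for p in range(n_seeded):
        positions[p] = complete_orientation(seed_structure, rng).adjacency()
    p_edge = min(0.5, 2.0 / max(n - 1, 1))
    for p in range(n_seeded, P):
        raw = (rng.random((n, n)) < p_edge).astype(np.int8)
        positions[p] = repair_acyclic(raw)
    velocities = rng.uniform(-1.0, 1.0, size=(P, n, n))

    scores = np.array([score_adj(positions[p]) for p in range(P)])
    pbest_pos = positions.copy()
    pbest_score = scores.copy()
    g = int(np.argmax(scores))
    gbest_pos = positions[g].copy()
    gbest_score = float(scores[g])
    trace = [gbest_score]

    for _ in range(params.n_iterations):
        r1 = rng.random((P, n, n))
        r2 = rng.random((P, n, n))
        velocities = (params.inertia * velocities
                      + params.cognitive * r1 * (pbest_pos - positions)
                      + params.social * r2 * (gbest_pos[None] - positions))
        np.clip(velocities, -params.v_max, params.v_max, out=velocities)
        flips = rng.random((P, n, n))
        positions = (flips < _sigmoid(velocities)).astype(np.int8)
        for p in range(P):
            positions[p] = repair_acyclic(positions[p])
            s = score_adj(positions[p])
            if s > pbest_score[p]:
                pbest_score[p] = s
                pbest_pos[p] = positions[p]
                if s > gbest_score:
                    gbest_score = float(s)
                    gbest_pos = positions[p].copy()
        trace.append(gbest_score)

    best = DirectedAcyclicStructure.from_adjacency(variables, gbest_pos, validate=True)
    return best, gbest_score, trace


def hill_climb(score_fn: Callable[[DirectedAcyclicStructure], float],
               start: DirectedAcyclicStructure,
               max_rounds: int = 200) -> tuple[DirectedAcyclicStructure, float]:
    """Steepest-ascent local search over single-arc moves.

    From ``start``, repeatedly applies the best-scoring arc addition,
    deletion or reversal (rejecting cyclic candidates) until no move
    improves the score.  Deterministic; used to polish the swarm's global
    best, whose bit-flip dynamics are poor at the final fine-grained
    exploitation.
    """
    variables = start.variables
    n = len(variables)
    score_adj = getattr(score_fn, "score_adjacency", None)
    if score_adj is None:
        def score_adj(adj: np.ndarray) -> float:  # type: ignore[misc]
            return score_fn(DirectedAcyclicStructure.from_adjacency(
                variables, adj, validate=False))

    adj = start.adjacency()
    current = score_adj(adj)
    for _ in range(max_rounds):
        best_move = None
        best_score = current
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                candidates = []
                if adj[i, j]:
                    delete = adj.copy()
                    delete[i, j] = 0
                    candidates.append(delete)
                    reverse = delete.copy()
                    reverse[j, i] = 1
                    candidates.append(reverse)
                elif not adj[j, i]:
                    add = adj.copy()
                    add[i, j] = 1
                    candidates.append(add)
                for cand in candidates:
                    if _find_cycle(cand) is not None:
                        continue
                    s = score_adj(cand)
                    if s > best_score:
                        best_score = s
                        best_move = cand
        if best_move is None:
            break
        adj = best_move
        current = best_score
    return DirectedAcyclicStructure.from_adjacency(variables, adj, validate=True), current
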