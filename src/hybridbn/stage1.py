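"""Stage 1: constraint-based initial structure plus knowledge rules.

The initial structure is built in two passes: a dependence screen keeps an
undirected edge for every pair whose maximal-information-coefficient style
score exceeds a threshold (optionally pruned by conditional-independence
tests), then unshielded triples are oriented into v-structures.  Fused
expert knowledge then edits the graph through four probabilistic rules:

* Rule 1 -- vague "associated" knowledge adds undirected edges;
* Rule 3 -- explicit "no edge" knowledge deletes undirected edges;
* Rule 2 -- vague "not a parent" knowledge deletes directed arcs;
* Rule 4 -- explicit arc knowledge inserts directed arcs.

Rules 1 and 3 run on the undirected skeleton, Rules 2 and 4 on the
partially directed graph after v-structure orientation.  Each rule fires
independently with probability equal to the knowledge's credibility theta,
consuming exactly one uniform draw per item so that runs are reproducible
by seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .knowledge import FusedKnowledge
from .model import DiscreteDataset, PartialStructure, enumerate_node_pairs

__all__ = ["mic_score", "ci_test", "build_skeleton", "orient_head_to_head",
           "modify_undirected", "modify_partial", "learn_initial_structure",
           "RuleLogEntry"]


# ---------------------------------------------------------------------------
# pairwise dependence score
# ---------------------------------------------------------------------------

def _partitions(n_cats: int, k: int):
    """Contiguous partitions of n_cats ordered categories into k groups."""
    for cuts in combinations(range(1, n_cats), k - 1):
        bounds = (0,) + cuts + (n_cats,)
        yield [range(bounds[t], bounds[t + 1]) for t in range(k)]


def _grid_score(counts: np.ndarray) -> float:
    """Mutual information of a 2-d contingency table over its minimum
    marginal entropy (0 when either margin is degenerate)."""
    n = counts.sum()
    p = counts / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    h_min = min(hx, hy)
    if h_min <= 0.0:
        return 0.0
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / np.outer(px, py)[nz])))
    return min(1.0, max(0.0, mi / h_min))


def mic_score(x: Sequence[int], y: Sequence[int]) -> float:
    """Normalized maximal-information dependence score for discrete vectors.

    The joint contingency table is evaluated on every grid obtained by
    merging adjacent categories of each axis, with the total number of cells
    bounded by n^0.6 (the native category grid is always admissible), and
    the best normalized mutual information is returned.  The score is
    symmetric, lies in [0, 1], equals 1 for identical variables and is near
    0 for independent ones.  Constant input yields 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    rx = int(xi.max()) + 1
    ry = int(yi.max()) + 1
    if rx < 2 or ry < 2:
        return 0.0

    counts = np.zeros((rx, ry))
    np.add.at(counts, (xi, yi), 1.0)
    best = _grid_score(counts)  # native grid, always admissible

    max_cells = max(4.0, n ** 0.6)
    # merged grids only pay off for small arities; bail out when the
    # composition count would explode (benchmark data has arity <= 4)
    if rx <= 12 and ry <= 12:
        for kx in range(2, rx + 1):
            for ky in range(2, ry + 1):
                if (kx, ky) == (rx, ry) or kx * ky > max_cells:
                    continue
                for gx in _partitions(rx, kx):
                    rows = np.stack([counts[list(g)].sum(axis=0) for g in gx])
                    for gy in _partitions(ry, ky):
                        merged = np.stack([rows[:, list(g)].sum(axis=1) for g in gy], axis=1)
                        best = max(best, _grid_score(merged))
    return best


# ---------------------------------------------------------------------------
# conditional independence testing
# ---------------------------------------------------------------------------

def ci_test(x: str, y: str, z: Sequence[str], data: DiscreteDataset,
            alpha: float = 0.05) -> tuple[float, float, bool]:
    """G^2 (likelihood-ratio) test of X independent of Y given Z.

    Returns ``(statistic, p_value, independent)`` with
    ``independent = p_value > alpha``.  Degrees of freedom are
    (r_x - 1)(r_y - 1) times the product of the conditioning arities;
    empty conditioning strata contribute nothing to the statistic.
    """
    if x in z or y in z:
        raise ValueError("conditioning set must exclude the tested pair")
    names = [v.name for v in data.variables]
    arity = {v.name: v.arity for v in data.variables}
    xv = data.records[:, names.index(x)]
    yv = data.records[:, names.index(y)]
    rx, ry = arity[x], arity[y]
    if z:
        zcols = data.records[:, [names.index(s) for s in z]]
        z_arities = [arity[s] for s in z]
        strata = np.zeros(data.n_records, dtype=np.int64)
        for t, r in enumerate(z_arities):
            strata = strata * r + zcols[:, t]
        n_strata = int(np.prod(z_arities))
    else:
        strata = np.zeros(data.n_records, dtype=np.int64)
        n_strata = 1

    flat = (strata * rx + xv) * ry + yv
    table = np.bincount(flat, minlength=n_strata * rx * ry).reshape(n_strata, rx, ry)

    g2 = 0.0
    for s in range(n_strata):
        obs = table[s].astype(float)
        ns = obs.sum()
        if ns == 0:
            continue
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / ns
        nz = obs > 0
        g2 += 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / expected[nz])))
    dof = (rx - 1) * (ry - 1) * n_strata
    p_value = float(chi2.sf(g2, dof)) if dof > 0 else 1.0
    return g2, p_value, p_value > alpha


def _find_sepset(x: str, y: str, h: PartialStructure, data: DiscreteDataset,
                 alpha: float, max_cond: int) -> tuple[str, ...] | None:
    """Smallest separating set among current neighbors, or None."""
    candidates = sorted(set(h.neighbors(x)) | set(h.neighbors(y)) - {x, y},
                        key=h.names.index)
    candidates = [c for c in candidates if c not in (x, y)]
    for size in range(0, max_cond + 1):
        for subset in combinations(candidates, size):
            _, _, independent = ci_test(x, y, subset, data, alpha)
            if independent:
                return subset
    return None


def build_skeleton(data: DiscreteDataset, tau: float = 0.1, alpha: float = 0.05,
                   max_cond: int = 3, prune: bool = True) -> PartialStructure:
    """Undirected skeleton: dependence screen then CI-test pruning.

    An edge is kept for every pair whose :func:`mic_score` exceeds ``tau``;
    with ``prune=True`` an edge is then removed whenever some conditioning
    subset of the endpoints' current neighbors (size at most ``max_cond``)
    renders the pair conditionally independent.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    names = [v.name for v in data.variables]
    h = PartialStructure(data.variables)
    for i, j in enumerate_node_pairs(len(names)):
        if mic_score(data.records[:, i], data.records[:, j]) > tau:
            h.undirected_edges.add((names[i], names[j]))
    if prune:
        for size in range(0, max_cond + 1):
            for (x, y) in sorted(h.undirected_edges,
                                 key=lambda e: (names.index(e[0]), names.index(e[1]))):
                candidates = [c for c in sorted(set(h.neighbors(x)) | set(h.neighbors(y)),
                                                key=names.index) if c not in (x, y)]
                if len(candidates) < size:
                    continue
                for subset in combinations(candidates, size):
                    _, _, independent = ci_test(x, y, subset, data, alpha)
                    if independent:
                        h.undirected_edges.discard((x, y))
                        break
    return h


def orient_head_to_head(skeleton: PartialStructure, data: DiscreteDataset,
                        alpha: float = 0.05, max_cond: int = 3) -> PartialStructure:
    """Orient unshielded triples x - z - y with non-adjacent x, y as
    v-structures x -> z <- y when conditioning on z induces dependence.

    For each such triple the smallest separating set of (x, y) over the
    endpoints' neighbors is sought; if one exists and excludes z, the
    collider is oriented.  An edge already oriented by an earlier triple is
    left as first oriented.
    """
    h = skeleton.copy()
    names = h.names
    for z in names:
        nbrs = sorted(h.neighbors(z), key=names.index)
        for x, y in combinations(nbrs, 2):
            if h.is_adjacent(x, y):
                continue
            sepset = _find_sepset(x, y, h, data, alpha, max_cond)
            if sepset is None or z in sepset:
                continue
            # orient both legs toward z unless an earlier triple fixed them
            for tail in (x, y):
                if h.has_undirected(tail, z):
                    h.undirected_edges.discard(h.canonical_pair(tail, z))
                    h.directed_arcs.add((tail, z))
    return h


# ---------------------------------------------------------------------------
# knowledge rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleLogEntry:
    """One rule application: pair, rule number, theta, draw, action taken."""

    pair: tuple[str, str]
    rule: int
    theta: float
    draw: float
    action: str

    def as_tsv(self) -> str:
        return (f"{self.pair[0]}-{self.pair[1]}\trule{self.rule}\t"
                f"{self.theta:.6g}\t{self.draw:.6g}\t{self.action}")


def _pair_sort_key(names: Sequence[str]):
    index = {n: i for i, n in enumerate(names)}

    def key(pair: tuple[str, str]):
        i, j = index[pair[0]], index[pair[1]]
        return (min(i, j), max(i, j))

    return key


def modify_undirected(h: PartialStructure, fused: FusedKnowledge,
                      rng: np.random.Generator,
                      log: list[RuleLogEntry] | None = None) -> PartialStructure:
    """Apply Rule 1 (vague add) then Rule 3 (explicit delete) to an
    undirected graph.  Each item consumes exactly one uniform draw and fires
    iff the draw falls in the open interval (0, theta)."""
    if h.directed_arcs:
        raise ValueError("modify_undirected expects an undirected structure")
    out = h.copy()
    key = _pair_sort_key(out.names)
    for (x, y) in sorted(fused.ie, key=key):
        theta = fused.ie[(x, y)]
        draw = float(rng.random())
        fired = 0.0 < draw < theta
        if fired:
            out.undirected_edges.add(out.canonical_pair(x, y))
        if log is not None:
            log.append(RuleLogEntry((x, y), 1, theta, draw,
                                    "add-edge" if fired else "no-op"))
    for (x, y) in sorted(fused.ca, key=key):
        theta = fused.ca[(x, y)]
        draw = float(rng.random())
        fired = 0.0 < draw < theta
        if fired:
            out.undirected_edges.discard(out.canonical_pair(x, y))
        if log is not None:
            log.append(RuleLogEntry((x, y), 3, theta, draw,
                                    "delete-edge" if fired else "no-op"))
    return out


def modify_partial(h: PartialStructure, fused: FusedKnowledge,
                   rng: np.random.Generator,
                   log: list[RuleLogEntry] | None = None) -> PartialStructure:
    """Apply Rule 2 (vague arc delete) then Rule 4 (explicit arc insert) to
    a partially directed graph.

    Rule 2 removes the directed arc <X, Y> asserted absent; undirected
    edges are not touched.  Rule 4 inserts <X, Y>, replacing an undirected
    (X, Y) edge or an opposite arc <Y, X>, unless the insertion would close
    a directed cycle, in which case it is skipped (and logged).
    """
    out = h.copy()
    key = _pair_sort_key(out.names)
    for (x, y) in sorted(fused.ia, key=key):
        theta = fused.ia[(x, y)]
        draw = float(rng.random())
        fired = 0.0 < draw < theta
        action = "no-op"
        if fired and (x, y) in out.directed_arcs:
            out.directed_arcs.discard((x, y))
            action = "delete-arc"
        if log is not None:
            log.append(RuleLogEntry((x, y), 2, theta, draw, action))
    for (x, y) in sorted(fused.ce, key=key):
        theta = fused.ce[(x, y)]
        draw = float(rng.random())
        fired = 0.0 < draw < theta
        action = "no-op"
        if fired and (x, y) not in out.directed_arcs:
            removed = frozenset({(y, x)} & out.directed_arcs)
            if out.directed_would_cycle((x, y), removed):
                action = "skip-cycle"
            else:
                out.directed_arcs -= removed
                out.undirected_edges.discard(out.canonical_pair(x, y))
                out.directed_arcs.add((x, y))
                action = "add-arc"
        elif fired:
            action = "already-present"
        if log is not None:
            log.append(RuleLogEntry((x, y), 4, theta, draw, action))
    return out


def learn_initial_structure(data: DiscreteDataset,
                            fused: FusedKnowledge | None = None,
                            rng: np.random.Generator | None = None,
                            tau: float = 0.1, alpha: float = 0.05,
                            max_cond: int = 3, prune: bool = True,
                            log: list[RuleLogEntry] | None = None) -> PartialStructure:
    """Full stage-1 pipeline.

    Skeleton, then Rules 1 and 3 on the undirected graph, then v-structure
    orientation, then Rules 2 and 4 on the partial graph.  With no fused
    knowledge the rule phases are skipped and the output is the plain
    constraint-based initial structure.
    """
    h = build_skeleton(data, tau=tau, alpha=alpha, max_cond=max_cond, prune=prune)
    if fused is not None and len(fused):
        if rng is None:
            raise ValueError("a random generator is required to apply knowledge rules")
        h = modify_undirected(h, fused, rng, log=log)
    h = orient_head_to_head(h, data, alpha=alpha, max_cond=max_cond)
    if fused is not None and len(fused):
        h = modify_partial(h, fused, rng, log=log)
    return h
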