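"""Decomposable data scores and knowledge-penalized scores.

Data scores (log-likelihood, BIC, BDeu) decompose over node families.  The
knowledge-penalized scores add, for every expert statement, the log
probability of that statement given the candidate structure's edge state on
the pair and the expert's accuracies:

* ``explicit_accuracy_score`` = BDeu log marginal likelihood + explicit
  penalty (the explicit-knowledge baseline score);
* ``evbic`` = BIC + explicit penalty + k * vague penalty, the
  explicit-vague BIC with vague statements down-weighted by ``k``
  (default 0.5, since each vague statement leaves two edge states open).

Statements are scored per expert and per item (no fusion here; fusion is a
stage-1 device).  A statement the structure makes impossible under the
expert's accuracies contributes ``ln(1e-12)`` rather than minus infinity so
search stays well-defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .knowledge import (ExpertAccuracy, KnowledgeItem,
                        knowledge_likelihood_explicit, knowledge_likelihood_vague)
from .model import (DiscreteBayesNet, DiscreteDataset, DirectedAcyclicStructure,
                    EdgeState, enumerate_node_pairs)

__all__ = ["ScoreBreakdown", "log_likelihood", "bic", "bdeu_log_marginal",
           "explicit_penalty", "vague_penalty", "evbic",
           "explicit_accuracy_score", "StructureScorer"]

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class ScoreBreakdown:
    """The three parts of a knowledge-penalized score.

    ``total = data_term + explicit_penalty + k * vague_penalty``.
    """

    data_term: float
    explicit_penalty: float
    vague_penalty: float
    k: float
    total: float

    def __post_init__(self) -> None:
        expected = self.data_term + self.explicit_penalty + self.k * self.vague_penalty
        if not math.isclose(self.total, expected, abs_tol=1e-9, rel_tol=0.0):
            raise ValueError("total does not match its components")


def _family_counts(data: DiscreteDataset, child: str,
                   parents: Sequence[str]) -> np.ndarray:
    """Sufficient statistics m_jk: counts of (parent configuration, state)."""
    names = [v.name for v in data.variables]
    arity = {v.name: v.arity for v in data.variables}
    child_col = data.records[:, names.index(child)]
    r = arity[child]
    if parents:
        rows = np.zeros(data.n_records, dtype=np.int64)
        for p in parents:
            rows = rows * arity[p] + data.records[:, names.index(p)]
        q = int(np.prod([arity[p] for p in parents]))
    else:
        rows = np.zeros(data.n_records, dtype=np.int64)
        q = 1
    flat = rows * r + child_col
    return np.bincount(flat, minlength=q * r).reshape(q, r).astype(float)


def _family_ll(counts: np.ndarray) -> float:
    m_j = counts.sum(axis=1, keepdims=True)
    nz = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(nz, counts / np.where(m_j > 0, m_j, 1.0), 1.0)
    return float(np.sum(counts[nz] * np.log(ratios[nz])))


def log_likelihood(data: DiscreteDataset, g: DirectedAcyclicStructure) -> float:
    """Maximum-likelihood log score: sum over families of m_jk ln(m_jk / m_j)."""
    _check_match(data, g)
    return sum(_family_ll(_family_counts(data, v.name, g.parents(v.name)))
               for v in g.variables)


def bic(data: DiscreteDataset, g: DirectedAcyclicStructure) -> float:
    """Log-likelihood penalized by (ln N)/2 times the free-parameter count."""
    _check_match(data, g)
    n = data.n_records
    dims = 0
    for v in g.variables:
        q = int(np.prod([g.arity(p) for p in g.parents(v.name)])) \
            if g.parents(v.name) else 1
        dims += q * (v.arity - 1)
    return log_likelihood(data, g) - 0.5 * math.log(n) * dims


def _family_bdeu(counts: np.ndarray, ess: float) -> float:
    q, r = counts.shape
    a_jk = ess / (q * r)
    a_j = ess / q
    m_j = counts.sum(axis=1)
    return float(np.sum(gammaln(a_j) - gammaln(a_j + m_j))
                 + np.sum(gammaln(a_jk + counts) - gammaln(a_jk)))


def bdeu_log_marginal(data: DiscreteDataset, g: DirectedAcyclicStructure,
                      ess: float = 1.0) -> float:
    """BDeu log marginal likelihood with uniform hyperparameters ess/(q r)."""
    if ess <= 0:
        raise ValueError("equivalent sample size must be positive")
    _check_match(data, g)
    return sum(_family_bdeu(_family_counts(data, v.name, g.parents(v.name)), ess)
               for v in g.variables)


def _check_match(data: DiscreteDataset, g: DirectedAcyclicStructure) -> None:
    if tuple(data.variables) != tuple(g.variables):
        raise ValueError("dataset and structure variables do not match")


def _log_floor(p: float) -> float:
    return math.log(max(p, PROB_FLOOR))


def explicit_penalty(g: DirectedAcyclicStructure,
                     items: Iterable[KnowledgeItem],
                     accuracies: Mapping[int, ExpertAccuracy]) -> float:
    """Sum of ln P(explicit statement | edge state in g) over all items."""
    total = 0.0
    for it in items:
        if not it.kind.is_explicit:
            raise ValueError(f"item {it} is not explicit")
        p = knowledge_likelihood_explicit(it.kind, g.pair_state(it.x, it.y),
                                          accuracies[it.expert_id])
        total += _log_floor(p)
    return total


def vague_penalty(g: DirectedAcyclicStructure,
                  items: Iterable[KnowledgeItem],
                  accuracies: Mapping[int, ExpertAccuracy]) -> float:
    """Sum of ln P(vague statement | edge state in g) over all items."""
    total = 0.0
    for it in items:
        if not it.kind.is_vague:
            raise ValueError(f"item {it} is not vague")
        p = knowledge_likelihood_vague(it.kind, g.pair_state(it.x, it.y),
                                       accuracies[it.expert_id])
        total += _log_floor(p)
    return total


def evbic(data: DiscreteDataset, g: DirectedAcyclicStructure,
          items: Iterable[KnowledgeItem],
          accuracies: Mapping[int, ExpertAccuracy],
          k: float = 0.5) -> ScoreBreakdown:
    """Explicit-vague BIC: BIC + explicit penalty + k * vague penalty."""
    if not 0.0 <= k <= 1.0:
        raise ValueError("k must lie in [0, 1]")
    items = list(items)
    data_term = bic(data, g)
    exp_pen = explicit_penalty(g, [it for it in items if it.kind.is_explicit], accuracies)
    vag_pen = vague_penalty(g, [it for it in items if it.kind.is_vague], accuracies)
    return ScoreBreakdown(data_term, exp_pen, vag_pen, k,
                          data_term + exp_pen + k * vag_pen)


def explicit_accuracy_score(data: DiscreteDataset, g: DirectedAcyclicStructure,
                            items: Iterable[KnowledgeItem],
                            accuracies: Mapping[int, ExpertAccuracy],
                            ess: float = 1.0) -> float:
    """Baseline explicit-knowledge score: BDeu marginal + explicit penalty."""
    items = [it for it in items if it.kind.is_explicit]
    return bdeu_log_marginal(data, g, ess) + explicit_penalty(g, items, accuracies)


# ---------------------------------------------------------------------------
# cached evaluator for search
# ---------------------------------------------------------------------------

class StructureScorer:
    """Fast decomposable evaluator over adjacency matrices.

    Family scores are cached by (node, parent set); per-pair knowledge
    penalties are precomputed for the three edge states, so evaluating a
    candidate costs one cache lookup per node plus one table lookup per
    annotated pair.  ``score='bic'`` ignores knowledge; ``'evbic'`` adds the
    penalized terms; ``'explicit'`` is the BDeu-based baseline.
    """

    def __init__(self, data: DiscreteDataset,
                 items: Sequence[KnowledgeItem] = (),
                 accuracies: Mapping[int, ExpertAccuracy] | None = None,
                 score: str = "evbic", k: float = 0.5, ess: float = 1.0):
        if score not in ("bic", "evbic", "explicit"):
            raise ValueError(f"unknown score {score!r}")
        self.data = data
        self.score_name = score
        self.k = k
        self.ess = ess
        self.names = [v.name for v in data.variables]
        self.arities = np.array([v.arity for v in data.variables])
        self.log_n = math.log(data.n_records)
        self._records = data.records
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

        # per-pair penalty table: penalty[(i, j)][state] for i < j,
        # state indexed FORWARD, REVERSE, ABSENT
        self._pair_penalty: dict[tuple[int, int], np.ndarray] = {}
        if items and score != "bic":
            if accuracies is None:
                raise ValueError("accuracies are required to score knowledge")
            index = {n: i for i, n in enumerate(self.names)}
            for it in items:
                i, j = index[it.x], index[it.y]
                canon = it if i < j else it.reoriented(it.y, it.x)
                ci, cj = min(i, j), max(i, j)
                if score == "explicit" and not canon.kind.is_explicit:
                    continue
                weight = 1.0 if canon.kind.is_explicit else self.k
                tree = (knowledge_likelihood_explicit if canon.kind.is_explicit
                        else knowledge_likelihood_vague)
                acc = accuracies[it.expert_id]
                vec = np.array([
                    _log_floor(tree(canon.kind, s, acc))
                    for s in (EdgeState.FORWARD, EdgeState.REVERSE, EdgeState.ABSENT)
                ]) * weight
                key = (ci, cj)
                self._pair_penalty[key] = self._pair_penalty.get(key, 0.0) + vec

    # -- family terms ----------------------------------------------------
    def family_score(self, node: int, parents: tuple[int, ...]) -> float:
        key = (node, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        r = int(self.arities[node])
        if parents:
            rows = np.zeros(self._records.shape[0], dtype=np.int64)
            for p in parents:
                rows = rows * int(self.arities[p]) + self._records[:, p]
            q = int(np.prod(self.arities[list(parents)]))
        else:
            rows = np.zeros(self._records.shape[0], dtype=np.int64)
            q = 1
        counts = np.bincount(rows * r + self._records[:, node],
                             minlength=q * r).reshape(q, r).astype(float)
        if self.score_name == "explicit":
            value = _family_bdeu(counts, self.ess)
        else:
            value = _family_ll(counts) - 0.5 * self.log_n * q * (r - 1)
        self._cache[key] = value
        return value

    # -- full-structure evaluation ---------------------------------------
    def score_adjacency(self, adj: np.ndarray) -> float:
        total = 0.0
        n = adj.shape[0]
        for j in range(n):
            parents = tuple(int(i) for i in np.nonzero(adj[:, j])[0])
            total += self.family_score(j, parents)
        for (i, j), vec in self._pair_penalty.items():
            if adj[i, j]:
                total += vec[0]
            elif adj[j, i]:
                total += vec[1]
            else:
                total += vec[2]
        return total

    def __call__(self, structure: DirectedAcyclicStructure) -> float:
        return self.score_adjacency(structure.adjacency())
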