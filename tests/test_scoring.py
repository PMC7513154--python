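"""Data scores (LL/BIC/BDeu) and knowledge-penalized scores."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate

from hybridbn import (DiscreteDataset, DirectedAcyclicStructure, ExpertAccuracy,
                      KnowledgeItem, KnowledgeKind, StructureScorer, Variable,
                      bdeu_log_marginal, bic, evbic, explicit_accuracy_score,
                      explicit_penalty, forward_sample, log_likelihood,
                      random_cpts, vague_penalty)
from hybridbn.scoring import ScoreBreakdown

from conftest import binary_vars, enumerate_all_dags, random_dag


def _dataset(names, records):
    records = np.asarray(records)
    variables = tuple(Variable(n, max(2, int(records[:, i].max()) + 1))
                      for i, n in enumerate(names))
    return DiscreteDataset(variables, records)


def _single_binary_7_of_10():
    return _dataset(["X"], np.array([[1]] * 7 + [[0]] * 3))


class TestLogLikelihood:
    def test_single_binary_closed_form(self):
        data = _single_binary_7_of_10()
        g = DirectedAcyclicStructure(data.variables)
        expected = 7 * math.log(0.7) + 3 * math.log(0.3)
        assert log_likelihood(data, g) == pytest.approx(expected, abs=1e-9)

    def test_uniform_counts_closed_form(self):
        data = _dataset(["X"], np.array([[0], [1], [2], [0], [1], [2]]))
        g = DirectedAcyclicStructure(data.variables)
        assert log_likelihood(data, g) == pytest.approx(6 * math.log(1 / 3), abs=1e-9)

    def test_adding_arc_never_decreases_ll(self, chain_bn):
        data = forward_sample(chain_bn, 300, seed=8)
        rng = np.random.default_rng(1)
        variables = data.variables
        for _ in range(10):
            g = random_dag(list(variables), rng)
            absent = [(x.name, y.name) for x in variables for y in variables
                      if x != y and g.pair_state(x.name, y.name).value == "absent"]
            if not absent:
                continue
            x, y = absent[rng.integers(len(absent))]
            try:
                g2 = DirectedAcyclicStructure(variables, set(g.arcs) | {(x, y)})
            except ValueError:
                continue
            assert log_likelihood(data, g2) >= log_likelihood(data, g) - 1e-9


class _ReferenceBic:
    """Independent textbook BIC: pandas groupby counting, no shared code."""

    @staticmethod
    def score(data, g):
        import pandas as pd
        frame = pd.DataFrame(data.records, columns=[v.name for v in data.variables])
        n = len(frame)
        total = 0.0
        dims = 0
        for v in data.variables:
            parents = g.parents(v.name)
            q = 1
            for p in parents:
                q *= g.arity(p)
            dims += q * (v.arity - 1)
            if parents:
                for _, sub in frame.groupby(parents, observed=True):
                    counts = sub[v.name].value_counts()
                    m = counts.sum()
                    total += sum(c * math.log(c / m) for c in counts)
            else:
                counts = frame[v.name].value_counts()
                total += sum(c * math.log(c / n) for c in counts)
        return total - 0.5 * math.log(n) * dims


class TestBic:
    def test_single_binary_closed_form(self):
        data = _single_binary_7_of_10()
        g = DirectedAcyclicStructure(data.variables)
        expected = 7 * math.log(0.7) + 3 * math.log(0.3) - 0.5 * math.log(10)
        assert bic(data, g) == pytest.approx(expected, abs=1e-9)

    def test_matches_independent_reference_on_random_structures(self, chain_bn):
        rng = np.random.default_rng(2)
        variables = binary_vars("A", "B", "C", "D")
        truth = random_dag(variables, rng)
        data = forward_sample(random_cpts(truth, seed=3), 400, seed=4)
        for _ in range(6):
            g = random_dag(variables, rng)
            assert bic(data, g) == pytest.approx(
                _ReferenceBic.score(data, g), abs=1e-6)

    def test_markov_equivalent_structures_score_equal(self):
        rng = np.random.default_rng(5)
        records = rng.integers(0, 2, size=(200, 2))
        records[:, 1] = (records[:, 0] + (rng.random(200) < 0.2)) % 2
        data = _dataset(["A", "B"], records)
        forward = DirectedAcyclicStructure(data.variables, [("A", "B")])
        backward = DirectedAcyclicStructure(data.variables, [("B", "A")])
        assert bic(data, forward) == pytest.approx(bic(data, backward), abs=1e-9)

    def test_decomposability(self, chain_bn):
        # changing one node's parent set changes only that node's local term
        data = forward_sample(chain_bn, 500, seed=6)
        g1 = DirectedAcyclicStructure(data.variables, [("A", "B")])
        g2 = DirectedAcyclicStructure(data.variables, [("A", "B"), ("B", "C")])
        scorer = StructureScorer(data, score="bic")
        delta_full = scorer.score_adjacency(g2.adjacency()) \
            - scorer.score_adjacency(g1.adjacency())
        idx = {v.name: i for i, v in enumerate(data.variables)}
        delta_local = scorer.family_score(idx["C"], (idx["B"],)) \
            - scorer.family_score(idx["C"], ())
        assert delta_full == pytest.approx(delta_local, abs=1e-9)


class TestBdeu:
    def test_single_observation_closed_form(self):
        data = _dataset(["X"], np.array([[1]]))
        g = DirectedAcyclicStructure(data.variables)
        assert bdeu_log_marginal(data, g, ess=1.0) == pytest.approx(
            math.log(0.5), abs=1e-12)

    def test_matches_numeric_quadrature(self):
        # one binary node, ess=1 -> Beta(1/2, 1/2) prior on P(X=1)
        records = np.array([[1]] * 6 + [[0]] * 4)
        data = _dataset(["X"], records)
        g = DirectedAcyclicStructure(data.variables)

        def integrand(t):
            prior = t ** (-0.5) * (1 - t) ** (-0.5) / math.pi
            return prior * t ** 6 * (1 - t) ** 4

        expected, _ = integrate.quad(integrand, 0.0, 1.0)
        assert bdeu_log_marginal(data, g, ess=1.0) == pytest.approx(
            math.log(expected), abs=1e-4)

    def test_requires_positive_ess(self):
        data = _single_binary_7_of_10()
        g = DirectedAcyclicStructure(data.variables)
        with pytest.raises(ValueError):
            bdeu_log_marginal(data, g, ess=0.0)


ACC = ExpertAccuracy(0.8, 0.1, 0.7, 0.65, 0.15, 0.8)


class TestPenalties:
    def test_empty_items_zero(self, fig1_structure):
        assert explicit_penalty(fig1_structure, [], {}) == 0.0
        assert vague_penalty(fig1_structure, [], {}) == 0.0

    def test_single_explicit_item(self, fig1_structure):
        items = [KnowledgeItem(1, "A", "B", KnowledgeKind.ARC)]
        assert explicit_penalty(fig1_structure, items, {1: ACC}) == pytest.approx(
            math.log(0.8))

    def test_single_vague_item_direction_free(self, fig1_structure):
        items = [KnowledgeItem(1, "A", "B", KnowledgeKind.SOME_EDGE)]
        assert vague_penalty(fig1_structure, items, {1: ACC}) == pytest.approx(
            math.log(0.65))

    def test_vague_penalty_symmetric_under_pair_reversal(self, fig1_structure):
        fwd = [KnowledgeItem(1, "A", "B", KnowledgeKind.NOT_PARENT)]
        rev = [KnowledgeItem(1, "B", "A", KnowledgeKind.NOT_CHILD)]
        assert vague_penalty(fig1_structure, fwd, {1: ACC}) == pytest.approx(
            vague_penalty(fig1_structure, rev, {1: ACC}))

    def test_asserted_state_maximizes_explicit_penalty(self):
        g_states = {
            "forward": DirectedAcyclicStructure(binary_vars("A", "B"), [("A", "B")]),
            "reverse": DirectedAcyclicStructure(binary_vars("A", "B"), [("B", "A")]),
            "absent": DirectedAcyclicStructure(binary_vars("A", "B")),
        }
        items = [KnowledgeItem(1, "A", "B", KnowledgeKind.ARC)]
        scores = {k: explicit_penalty(g, items, {1: ACC})
                  for k, g in g_states.items()}
        assert max(scores, key=scores.get) == "forward"


class TestEvbic:
    def test_no_knowledge_equals_bic(self, chain_bn):
        data = forward_sample(chain_bn, 200, seed=1)
        g = DirectedAcyclicStructure(data.variables, [("A", "B")])
        breakdown = evbic(data, g, [], {}, k=0.5)
        assert breakdown.total == pytest.approx(bic(data, g), abs=1e-9)
        assert breakdown.explicit_penalty == 0.0 and breakdown.vague_penalty == 0.0

    def test_breakdown_invariant_enforced(self):
        with pytest.raises(ValueError):
            ScoreBreakdown(-10.0, -1.0, -2.0, 0.5, -10.0)

    def test_k_zero_removes_vague_influence(self, chain_bn):
        data = forward_sample(chain_bn, 200, seed=2)
        items = [KnowledgeItem(1, "A", "B", KnowledgeKind.NOT_PARENT)]
        g1 = DirectedAcyclicStructure(data.variables, [("A", "B")])
        g2 = DirectedAcyclicStructure(data.variables, [("B", "A")])
        gap_scored = (evbic(data, g1, items, {1: ACC}, k=0.0).total
                      - evbic(data, g2, items, {1: ACC}, k=0.0).total)
        gap_plain = bic(data, g1) - bic(data, g2)
        assert gap_scored == pytest.approx(gap_plain, abs=1e-12)

    def test_equivalence_broken_by_exactly_log_gamma_ratio(self, chain_bn):
        data = forward_sample(chain_bn, 500, seed=3)
        items = [KnowledgeItem(1, "A", "B", KnowledgeKind.ARC)]
        forward = DirectedAcyclicStructure(data.variables, [("A", "B")])
        backward = DirectedAcyclicStructure(data.variables, [("B", "A")])
        gap = (evbic(data, forward, items, {1: ACC}).total
               - evbic(data, backward, items, {1: ACC}).total)
        assert gap == pytest.approx(math.log(ACC.gamma1 / ACC.gamma2), abs=1e-9)

    def test_strong_contradicting_knowledge_moves_the_argmax(self):
        # data with a clear A-B association; five experts insist "no edge"
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, size=200)
        b = (a + (rng.random(200) < 0.3)) % 2
        c = rng.integers(0, 2, size=200)
        data = _dataset(["A", "B", "C"], np.column_stack([a, b, c]))
        # ten experts whose "no edge" reports are nearly impossible under a
        # true arc (small residual 1 - gamma1 - gamma2): the joint penalty
        # outweighs the data term's preference for the A-B edge
        sure = ExpertAccuracy(0.85, 0.1, 0.95, 0.85, 0.1, 0.95)
        items = [KnowledgeItem(i, "A", "B", KnowledgeKind.NO_EDGE)
                 for i in range(1, 11)]
        accs = {i: sure for i in range(1, 11)}
        dags = enumerate_all_dags(list(data.variables))
        assert len(dags) == 25
        best_bic = max(dags, key=lambda g: bic(data, g))
        best_ev = max(dags, key=lambda g: evbic(data, g, items, accs).total)
        assert best_bic.pair_state("A", "B").value != "absent"
        assert best_ev.pair_state("A", "B").value == "absent"


class TestExplicitAccuracyScore:
    def test_no_knowledge_equals_bdeu(self, chain_bn):
        data = forward_sample(chain_bn, 200, seed=5)
        g = DirectedAcyclicStructure(data.variables, [("A", "B")])
        assert explicit_accuracy_score(data, g, [], {}) == pytest.approx(
            bdeu_log_marginal(data, g), abs=1e-12)

    def test_argmax_aligns_with_asserted_arc(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 2, size=300)
        b = (a + (rng.random(300) < 0.2)) % 2
        c = rng.integers(0, 2, size=300)
        data = _dataset(["A", "B", "C"], np.column_stack([a, b, c]))
        sure = ExpertAccuracy(0.95, 0.02, 0.9, 0.9, 0.05, 0.9)
        items = [KnowledgeItem(1, "A", "B", KnowledgeKind.ARC)]
        dags = enumerate_all_dags(list(data.variables))
        best = max(dags, key=lambda g: explicit_accuracy_score(
            data, g, items, {1: sure}))
        assert ("A", "B") in best.arcs
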