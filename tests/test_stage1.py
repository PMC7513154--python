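"""Stage 1: dependence score, CI tests, skeleton, orientation, knowledge rules."""

import numpy as np
import pytest

from hybridbn import (DiscreteBayesNet, DirectedAcyclicStructure, FusedKnowledge,
                      PartialStructure, Variable, build_skeleton, ci_test,
                      forward_sample, learn_initial_structure, mic_score,
                      modify_partial, modify_undirected, orient_head_to_head,
                      structural_diff)
from hybridbn.knowledge import ExpertAccuracy, simulate_experts, fuse_all
from hybridbn.stage1 import RuleLogEntry

from conftest import binary_vars, random_dag


class TestMicScore:
    def test_identical_variables_score_one(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, size=500)  # non-uniform categorical
        assert mic_score(x, x) == pytest.approx(1.0, abs=1e-6)

    def test_independent_variables_score_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=5000)
        y = rng.integers(0, 2, size=5000)
        assert mic_score(x, y) < 0.05

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.integers(0, 3, size=200)
            y = rng.integers(0, 4, size=200)
            assert mic_score(x, y) == pytest.approx(mic_score(y, x), abs=1e-12)

    def test_constant_vector_scores_zero(self):
        assert mic_score(np.zeros(100, dtype=int),
                         np.arange(100) % 2) == 0.0

    def test_deterministic_relabelling_scores_one(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, size=400)
        assert mic_score(x, 1 - x) == pytest.approx(1.0, abs=1e-6)


class TestCiTest:
    def test_type_one_error_rate(self):
        # independent pair: the test should accept independence ~1-alpha of the time
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            records = rng.integers(0, 2, size=(5000, 2))
            data = _dataset(["X", "Y"], records)
            _, _, independent = ci_test("X", "Y", [], data, alpha=0.05)
            hits += independent
        assert hits >= 90

    def test_deterministic_copy_strongly_dependent(self):
        x = np.arange(1000) % 2
        data = _dataset(["X", "Y"], np.column_stack([x, x]))
        _, p, independent = ci_test("X", "Y", [], data)
        assert p < 1e-6 and not independent

    def test_collider_induces_dependence_when_conditioned(self, collider_bn):
        # the causes are marginally independent but become dependent once
        # their common effect is conditioned on (explaining away)
        marginal_indep = conditional_dep = 0
        for seed in range(20):
            data = forward_sample(collider_bn, 5000, seed=seed)
            _, _, i1 = ci_test("X", "Y", [], data)
            _, _, i2 = ci_test("X", "Y", ["W"], data)
            marginal_indep += i1
            conditional_dep += not i2
        assert marginal_indep >= 15
        assert conditional_dep >= 19

    def test_conditioning_set_excludes_pair(self, collider_bn):
        data = forward_sample(collider_bn, 100, seed=0)
        with pytest.raises(ValueError):
            ci_test("X", "Y", ["X"], data)


def _dataset(names, records):
    from hybridbn import DiscreteDataset
    variables = tuple(Variable(n, int(records[:, i].max()) + 1)
                      for i, n in enumerate(names))
    return DiscreteDataset(variables, records)


class TestBuildSkeleton:
    def test_tau_one_gives_empty_skeleton(self, chain_bn):
        data = forward_sample(chain_bn, 500, seed=1)
        h = build_skeleton(data, tau=1.0)
        assert not h.undirected_edges

    def test_tau_zero_unpruned_gives_complete_graph(self, chain_bn):
        data = forward_sample(chain_bn, 500, seed=1)
        h = build_skeleton(data, tau=0.0, prune=False)
        assert len(h.undirected_edges) == 3

    def test_chain_prunes_endpoint_edge(self, chain_bn):
        data = forward_sample(chain_bn, 5000, seed=3)
        h = build_skeleton(data, tau=0.1)
        assert h.undirected_edges == {("A", "B"), ("B", "C")}


class TestOrientHeadToHead:
    def test_collider_is_oriented(self, collider_bn):
        hits = 0
        for seed in range(10):
            data = forward_sample(collider_bn, 5000, seed=seed)
            h = build_skeleton(data, tau=0.05)
            out = orient_head_to_head(h, data)
            hits += (out.directed_arcs == {("X", "W"), ("Y", "W")}
                     and not out.undirected_edges)
        assert hits >= 7  # fails only when a CI test errs on the skeleton

    def test_chain_left_undirected(self, chain_bn):
        data = forward_sample(chain_bn, 5000, seed=6)
        h = build_skeleton(data, tau=0.1)
        out = orient_head_to_head(h, data)
        assert not out.directed_arcs  # chain and fork are indistinguishable

    def test_no_unshielded_triple_is_identity(self, chain_bn):
        data = forward_sample(chain_bn, 500, seed=2)
        h = PartialStructure(data.variables, undirected_edges=[("A", "B")])
        out = orient_head_to_head(h, data)
        assert out.undirected_edges == {("A", "B")}
        assert not out.directed_arcs


class TestKnowledgeRules:
    def _empty_partial(self, *names):
        return PartialStructure(binary_vars(*names))

    def test_rule1_certain_knowledge_always_adds(self):
        h = self._empty_partial("A", "B")
        fused = FusedKnowledge(ie={("A", "B"): 1.0})
        out = modify_undirected(h, fused, np.random.default_rng(0))
        assert out.undirected_edges == {("A", "B")}

    def test_theta_zero_never_fires(self):
        h = PartialStructure(binary_vars("A", "B"), undirected_edges=[("A", "B")])
        fused = FusedKnowledge(ie={("A", "B"): 0.0}, ca={("A", "B"): 0.0})
        out = modify_undirected(h, fused, np.random.default_rng(0))
        assert out.undirected_edges == {("A", "B")}

    def test_rule3_deletes_undirected_edge(self):
        h = PartialStructure(binary_vars("A", "B"), undirected_edges=[("A", "B")])
        fused = FusedKnowledge(ca={("A", "B"): 1.0})
        out = modify_undirected(h, fused, np.random.default_rng(0))
        assert not out.undirected_edges

    def test_rule_firing_rate_matches_theta(self):
        theta = 0.8
        n = 10_000
        rng = np.random.default_rng(9)
        fused = FusedKnowledge(ie={("A", "B"): theta})
        fired = sum(
            bool(modify_undirected(self._empty_partial("A", "B"), fused, rng)
                 .undirected_edges)
            for _ in range(n))
        se = np.sqrt(theta * (1 - theta) / n)
        assert abs(fired / n - theta) < 3 * se

    def test_rule4_inserts_arc(self):
        out = modify_partial(self._empty_partial("A", "B"),
                             FusedKnowledge(ce={("A", "B"): 1.0}),
                             np.random.default_rng(0))
        assert out.directed_arcs == {("A", "B")}

    def test_rule4_replaces_undirected_edge(self):
        h = PartialStructure(binary_vars("A", "B"), undirected_edges=[("A", "B")])
        out = modify_partial(h, FusedKnowledge(ce={("A", "B"): 1.0}),
                             np.random.default_rng(0))
        assert out.directed_arcs == {("A", "B")} and not out.undirected_edges

    def test_rule2_deletes_directed_arc(self):
        h = PartialStructure(binary_vars("A", "B"), directed_arcs=[("A", "B")])
        out = modify_partial(h, FusedKnowledge(ia={("A", "B"): 1.0}),
                             np.random.default_rng(0))
        assert not out.directed_arcs

    def test_rule2_ignores_opposite_arc(self):
        h = PartialStructure(binary_vars("A", "B"), directed_arcs=[("B", "A")])
        out = modify_partial(h, FusedKnowledge(ia={("A", "B"): 1.0}),
                             np.random.default_rng(0))
        assert out.directed_arcs == {("B", "A")}

    def test_rule4_cycle_insertions_skipped(self):
        fused = FusedKnowledge(ce={("A", "B"): 1.0, ("B", "C"): 1.0,
                                   ("C", "A"): 1.0})
        log: list[RuleLogEntry] = []
        out = modify_partial(self._empty_partial("A", "B", "C"), fused,
                             np.random.default_rng(0), log=log)
        assert len(out.directed_arcs) == 2
        DirectedAcyclicStructure(out.variables, out.directed_arcs)  # acyclic
        assert any(e.action == "skip-cycle" for e in log)

    def test_empty_knowledge_is_identity(self, chain_bn):
        data = forward_sample(chain_bn, 1000, seed=4)
        h = build_skeleton(data, tau=0.1)
        fused = FusedKnowledge()
        rng = np.random.default_rng(0)
        assert modify_undirected(h, fused, rng).undirected_edges == h.undirected_edges
        out = modify_partial(h, fused, rng)
        assert (out.directed_arcs, out.undirected_edges) == \
            (h.directed_arcs, h.undirected_edges)

    def test_each_item_consumes_exactly_one_draw(self):
        fused = FusedKnowledge(ie={("A", "B"): 0.5}, ca={("A", "C"): 0.5})
        rng1 = np.random.default_rng(123)
        modify_undirected(self._empty_partial("A", "B", "C"), fused, rng1)
        rng2 = np.random.default_rng(123)
        rng2.random(2)
        assert rng1.random() == rng2.random()


class TestStage1Pipeline:
    def test_output_never_cyclic(self):
        rng = np.random.default_rng(10)
        for seed in range(5):
            variables = binary_vars(*[f"X{i}" for i in range(6)])
            truth = random_dag(variables, rng)
            from hybridbn import random_cpts
            bn = random_cpts(truth, seed=seed)
            data = forward_sample(bn, 500, seed=seed)
            items = simulate_experts(truth, _table_accs(), 1.0, "ev", rng)
            fused = fuse_all(items, _table_accs(), rng, variables=truth.names)
            h = learn_initial_structure(data, fused, rng)
            DirectedAcyclicStructure(h.variables, h.directed_arcs)  # must not raise

    def test_perfect_knowledge_does_not_hurt_on_average(self):
        """With perfect full-coverage explicit knowledge, mean SHD of the
        stage-1 output (directed part) is no worse than knowledge-free."""
        perfect = {1: ExpertAccuracy(1.0, 0.0, 1.0, 1.0, 0.0, 1.0)}
        shd_with, shd_without = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            variables = binary_vars(*[f"X{i}" for i in range(6)])
            truth = random_dag(variables, rng)
            from hybridbn import random_cpts
            bn = random_cpts(truth, seed=seed)
            data = forward_sample(bn, 800, seed=seed + 1000)
            items = simulate_experts(truth, perfect, 1.0, "explicit", rng)
            fused = fuse_all(items, perfect, rng, variables=truth.names)
            with_k = learn_initial_structure(data, fused, rng)
            plain = learn_initial_structure(data)
            shd_with.append(_directed_shd(with_k, truth))
            shd_without.append(_directed_shd(plain, truth))
        assert np.mean(shd_with) <= np.mean(shd_without)

    def test_perfect_knowledge_arcs_subset_of_truth(self):
        perfect = {1: ExpertAccuracy(1.0, 0.0, 1.0, 1.0, 0.0, 1.0)}
        rng = np.random.default_rng(77)
        variables = binary_vars(*[f"X{i}" for i in range(6)])
        truth = random_dag(variables, rng)
        from hybridbn import random_cpts
        data = forward_sample(random_cpts(truth, seed=5), 800, seed=5)
        items = simulate_experts(truth, perfect, 1.0, "explicit", rng)
        fused = fuse_all(items, perfect, rng, variables=truth.names)
        h = learn_initial_structure(data, fused, rng)
        # perfect explicit knowledge inserts only true arcs; deletions by
        # Rule 3 can only remove false edges
        assert h.directed_arcs <= truth.arcs


def _table_accs():
    from hybridbn import default_accuracies
    return default_accuracies()


def _directed_shd(h: PartialStructure, truth: DirectedAcyclicStructure) -> int:
    learned = DirectedAcyclicStructure(h.variables, h.directed_arcs)
    return structural_diff(learned, truth).shd
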