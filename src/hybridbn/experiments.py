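"""Benchmark fixtures, random CPT generation, and the experiment driver.

The driver replays the benchmark protocol: forward-sample datasets from a
ground-truth network, simulate heterogeneous experts at coverage fraction
``v``, learn a structure with the two-stage algorithm (knowledge applied in
stage 1, stage 2, or both), and compare the result with the truth.  Mean
(MR) and best (BR) results over replicates are tabulated per knowledge case
and coverage.

Benchmark CPTs are not part of the structure fixtures; unless the user
supplies a parameterized network file, rows are drawn from a symmetric
Dirichlet with a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .bpso import SwarmParams, bpso_search, hill_climb
from .evaluation import RunSummary, StructuralDiff, structural_diff, summarize_runs
from .knowledge import (ExpertAccuracy, KnowledgeItem, default_accuracies,
                        fuse_all, simulate_experts)
from .model import (DiscreteBayesNet, DiscreteDataset, DirectedAcyclicStructure,
                    Variable, forward_sample)
from .netio import read_network
from .scoring import StructureScorer, bic
from .stage1 import learn_initial_structure

__all__ = ["load_fixture", "random_cpts", "learn_structure",
           "ExperimentConfig", "ExperimentResult", "run_experiment",
           "write_summary_tsv"]

FIXTURES = ("asia", "alarm", "fig1")


def load_fixture(name: str) -> DirectedAcyclicStructure:
    """A packaged benchmark structure: ``asia`` (8 nodes, 8 arcs),
    ``alarm`` (37 nodes, 46 arcs) or the 4-node toy ``fig1``."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    ref = resources.files("hybridbn").joinpath(f"data/{name}.structure.tsv")
    variables: list[Variable] = []
    arcs: list[tuple[str, str]] = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, *rest = line.split("\t")
        if kind == "node":
            variables.append(Variable(rest[0], int(rest[1])))
        elif kind == "arc":
            arcs.append((rest[0], rest[1]))
        else:
            raise ValueError(f"bad fixture line: {line!r}")
    return DirectedAcyclicStructure(variables, arcs)


def random_cpts(g: DirectedAcyclicStructure,
                arities: Mapping[str, int] | None = None,
                concentration: float = 0.5,
                seed: int | np.random.Generator = 0) -> DiscreteBayesNet:
    """Equip a structure with CPT rows drawn from a symmetric Dirichlet.

    Small ``concentration`` yields skewed, near-deterministic rows (strong
    dependencies); large values approach uniform tables.  Deterministic for
    a fixed integer seed.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if arities:
        variables = tuple(Variable(v.name, arities.get(v.name, v.arity))
                          for v in g.variables)
        g = DirectedAcyclicStructure(variables, set(g.arcs))
    cpts = {}
    for v in g.variables:
        parents = g.parents(v.name)
        q = int(np.prod([g.arity(p) for p in parents])) if parents else 1
        cpts[v.name] = rng.dirichlet([concentration] * v.arity, size=q)
    return DiscreteBayesNet(g, cpts)


def learn_structure(data: DiscreteDataset,
                    items: Sequence[KnowledgeItem] = (),
                    accuracies: Mapping[int, ExpertAccuracy] | None = None,
                    placement: str = "both",
                    rng: np.random.Generator | int = 0,
                    tau: float = 0.1, alpha: float = 0.05, max_cond: int = 3,
                    k: float = 0.5,
                    swarm: SwarmParams = SwarmParams(),
                    refine: bool = True,
                    ) -> tuple[DirectedAcyclicStructure, float]:
    """Two-stage learner: constraint-based seed plus BPSO over a score.

    ``placement`` controls where knowledge enters: ``'stage1'`` applies the
    fusion rules to the initial structure and searches plain BIC,
    ``'stage2'`` searches the explicit-vague BIC from a knowledge-free seed,
    ``'both'`` does both.  With no items the learner is the knowledge-free
    hybrid baseline.  With ``refine=True`` the swarm's global best is
    polished by steepest-ascent single-arc moves.  Returns the best
    structure and its search score.
    """
    if placement not in ("stage1", "stage2", "both"):
        raise ValueError(f"unknown placement {placement!r}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    items = list(items)
    use_stage1 = bool(items) and placement in ("stage1", "both")
    use_stage2 = bool(items) and placement in ("stage2", "both")

    fused = None
    if use_stage1:
        if accuracies is None:
            raise ValueError("accuracies are required to use knowledge")
        fused = fuse_all(items, accuracies, rng,
                         variables=[v.name for v in data.variables])
    seed = learn_initial_structure(data, fused=fused, rng=rng,
                                   tau=tau, alpha=alpha, max_cond=max_cond)
    if use_stage2:
        scorer = StructureScorer(data, items, accuracies, score="evbic", k=k)
    else:
        scorer = StructureScorer(data, score="bic")
    best, best_score, _ = bpso_search(scorer, seed, swarm, rng)
    if refine:
        best, best_score = hill_climb(scorer, best)
    return best, best_score


@dataclass(frozen=True)
class ExperimentConfig:
    """One benchmark experiment: network x sample sizes x knowledge setup."""

    network: str = "asia"          # fixture name or path to a network file
    sample_sizes: tuple[int, ...] = (2000,)
    n_datasets: int = 10
    case: str = "none"             # none | explicit | vague | ev
    v_values: tuple[float, ...] = (0.4, 0.5, 0.6)
    placement: str = "both"        # stage1 | stage2 | both
    accuracies: Mapping[int, ExpertAccuracy] | None = None  # default: packaged table
    swarm: SwarmParams = SwarmParams()
    seed: int = 0
    tau: float = 0.1
    alpha: float = 0.05
    max_cond: int = 3
    k: float = 0.5
    concentration: float = 0.5
    cpt_seed: int = 20180620      # seed of the published random parameterization

    def __post_init__(self) -> None:
        if self.case not in ("none", "explicit", "vague", "ev"):
            raise ValueError(f"unknown knowledge case {self.case!r}")
        if self.placement not in ("stage1", "stage2", "both"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")


@dataclass
class ExperimentResult:
    """Per-cell replicate diffs/scores plus MR/BR summaries and a manifest."""

    config: ExperimentConfig
    truth: DirectedAcyclicStructure
    diffs: dict[tuple[int, float], list[StructuralDiff]]
    scores: dict[tuple[int, float], list[float]]
    failures: dict[tuple[int, float], list[str]]
    manifest: dict

    def summary(self, sample_size: int, v: float) -> RunSummary:
        key = (sample_size, v)
        return summarize_runs(self.diffs[key], self.scores[key])


def _resolve_truth(config: ExperimentConfig) -> DiscreteBayesNet:
    if config.network in FIXTURES:
        structure = load_fixture(config.network)
        return random_cpts(structure, concentration=config.concentration,
                           seed=config.cpt_seed)
    return read_network(Path(config.network))


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full protocol for one knowledge case.

    For each (sample size, v) cell, ``n_datasets`` replicates are run;
    replicate ``r`` pairs dataset ``r`` with expert-knowledge set ``r``.
    The learned structure's BIC (always plain BIC, for comparability across
    cases) and its structural diff against the truth are recorded.  With
    ``case='none'`` the v grid collapses to a single knowledge-free cell
    per sample size (reported under v = 0.0).
    """
    truth_bn = _resolve_truth(config)
    truth = truth_bn.structure
    accuracies = dict(config.accuracies) if config.accuracies else default_accuracies()
    v_grid = (0.0,) if config.case == "none" else tuple(config.v_values)

    master = np.random.SeedSequence(config.seed)
    diffs: dict[tuple[int, float], list[StructuralDiff]] = {}
    scores: dict[tuple[int, float], list[float]] = {}
    failures: dict[tuple[int, float], list[str]] = {}
    seeds_used: dict[str, int] = {}

    for si, n_samples in enumerate(config.sample_sizes):
        # datasets are shared across v values (and across cases when the
        # same master seed is reused), as in a paired design
        data_seeds = np.random.SeedSequence((config.seed, 1, si)).generate_state(
            config.n_datasets) % (2 ** 31)
        datasets = [forward_sample(truth_bn, n_samples, int(s)) for s in data_seeds]
        for vi, v in enumerate(v_grid):
            key = (n_samples, v)
            diffs[key] = []
            scores[key] = []
            failures[key] = []
            run_seeds = np.random.SeedSequence((config.seed, 2, si, vi)).generate_state(
                config.n_datasets) % (2 ** 31)
            for r in range(config.n_datasets):
                seeds_used[f"n{n_samples}_v{v}_rep{r}"] = int(run_seeds[r])
                rng = np.random.default_rng(int(run_seeds[r]))
                try:
                    if config.case == "none":
                        items: list[KnowledgeItem] = []
                    else:
                        items = simulate_experts(truth, accuracies, v,
                                                 config.case, rng)
                    learned, _ = learn_structure(
                        datasets[r], items, accuracies,
                        placement=config.placement, rng=rng,
                        tau=config.tau, alpha=config.alpha,
                        max_cond=config.max_cond, k=config.k,
                        swarm=config.swarm)
                    diffs[key].append(structural_diff(learned, truth))
                    scores[key].append(bic(datasets[r], learned))
                except Exception as exc:  # pragma: no cover - defensive
                    failures[key].append(f"replicate {r}: {exc!r}")

    manifest = {
        "network": config.network,
        "case": config.case,
        "placement": config.placement,
        "sample_sizes": list(config.sample_sizes),
        "v_values": list(v_grid),
        "n_datasets": config.n_datasets,
        "master_seed": config.seed,
        "cpt_seed": config.cpt_seed,
        "concentration": config.concentration,
        "tau": config.tau,
        "alpha": config.alpha,
        "max_cond": config.max_cond,
        "k": config.k,
        "swarm": {"n_particles": config.swarm.n_particles,
                  "n_iterations": config.swarm.n_iterations,
                  "inertia": config.swarm.inertia,
                  "cognitive": config.swarm.cognitive,
                  "social": config.swarm.social,
                  "v_max": config.swarm.v_max},
        "replicate_seeds": seeds_used,
    }
    return ExperimentResult(config, truth, diffs, scores, failures, manifest)


def write_summary_tsv(results: Mapping[str, ExperimentResult],
                      path: str | Path) -> None:
    """Tabulate MR/BR metrics per knowledge case, sample size and v."""
    lines = ["case\tsample_size\tv\tkind\tmetric\tvalue"]
    for case, result in results.items():
        for (n_samples, v), cell in sorted(result.diffs.items()):
            if not cell:
                continue
            summary = result.summary(n_samples, v)
            for metric, value in summary.rounded().items():
                kind, name = metric.split("_", 1)
                lines.append(f"{case}\t{n_samples}\t{v}\t{kind}\t{name}\t{value}")
    Path(path).write_text("\n".join(lines) + "\n")
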