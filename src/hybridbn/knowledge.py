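"""Expert knowledge: representation, credibility, fusion, simulation.

Six kinds of statement an expert can make about a node pair (X, Y), numbered
1-6:

===== ========== =====================================================
code  symbol     meaning
===== ========== =====================================================
1     ``->``     X is a parent of Y                       (explicit)
2     ``<-``     Y is a parent of X                       (explicit)
3     ``x``      X and Y are not associated               (explicit)
4     ``-``      X and Y are associated, direction unknown  (vague)
5     ``-/>``    X is not a parent of Y                     (vague)
6     ``</-``    Y is not a parent of X                     (vague)
===== ========== =====================================================

Each expert carries six accuracy parameters: gamma1/gamma2/gamma3 govern the
explicit statements (probability of reporting the correct orientation, the
reversed orientation, and of correctly detecting an absent edge) and
beta1/beta2/beta3 play the same roles for vague statements.

The *credibility* of a statement is the probability that it is true given
the expert's accuracies.  Conflicting statements from several experts about
the same pair are fused by roulette selection over credibility-weighted
kind probabilities; the fused statement keeps the mean credibility of its
supporters.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import DirectedAcyclicStructure, EdgeState, enumerate_node_pairs

__all__ = [
    "KnowledgeKind", "ExpertAccuracy", "KnowledgeItem", "FusedKnowledge",
    "credibility", "fuse_pair", "fuse_all",
    "knowledge_likelihood_explicit", "knowledge_likelihood_vague",
    "simulate_experts", "read_knowledge_csv", "write_knowledge_csv",
    "read_accuracies_csv", "write_accuracies_csv", "default_accuracies",
]


class KnowledgeKind(IntEnum):
    """The six kinds of expert statement (codes 1-6; 1-3 explicit, 4-6 vague)."""

    ARC = 1          # ->   X is a parent of Y
    REVERSED_ARC = 2  # <-   Y is a parent of X
    NO_EDGE = 3      # x    not associated
    SOME_EDGE = 4    # -    associated, direction unknown
    NOT_PARENT = 5   # -/>  X is not a parent of Y
    NOT_CHILD = 6    # </-  Y is not a parent of X

    @property
    def is_explicit(self) -> bool:
        return self.value <= 3

    @property
    def is_vague(self) -> bool:
        return self.value >= 4

    @property
    def symbol(self) -> str:
        return {1: "->", 2: "<-", 3: "x", 4: "-", 5: "-/>", 6: "</-"}[self.value]

    def flipped(self) -> "KnowledgeKind":
        """The same statement expressed on the reversed pair (Y, X)."""
        swap = {1: 2, 2: 1, 3: 3, 4: 4, 5: 6, 6: 5}
        return KnowledgeKind(swap[self.value])


EXPLICIT_KINDS = (KnowledgeKind.ARC, KnowledgeKind.REVERSED_ARC, KnowledgeKind.NO_EDGE)
VAGUE_KINDS = (KnowledgeKind.SOME_EDGE, KnowledgeKind.NOT_PARENT, KnowledgeKind.NOT_CHILD)


@dataclass(frozen=True)
class ExpertAccuracy:
    """Six accuracy parameters of one expert.

    gamma1 + gamma2 <= 1 and beta1 + beta2 <= 1 so the residual probability
    mass of each decision tree is nonnegative.
    """

    gamma1: float
    gamma2: float
    gamma3: float
    beta1: float
    beta2: float
    beta3: float

    def __post_init__(self) -> None:
        for name in ("gamma1", "gamma2", "gamma3", "beta1", "beta2", "beta3"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.gamma1 + self.gamma2 > 1.0 + 1e-12:
            raise ValueError("gamma1 + gamma2 must not exceed 1")
        if self.beta1 + self.beta2 > 1.0 + 1e-12:
            raise ValueError("beta1 + beta2 must not exceed 1")


@dataclass(frozen=True)
class KnowledgeItem:
    """One expert's statement about one ordered node pair."""

    expert_id: int
    x: str
    y: str
    kind: KnowledgeKind

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise ValueError("a knowledge item must concern two distinct variables")

    def reoriented(self, x: str, y: str) -> "KnowledgeItem":
        """The same statement expressed on the ordered pair (x, y)."""
        if (self.x, self.y) == (x, y):
            return self
        if (self.y, self.x) == (x, y):
            return KnowledgeItem(self.expert_id, x, y, self.kind.flipped())
        raise ValueError("pair mismatch")


def credibility(kind: KnowledgeKind, acc: ExpertAccuracy) -> float:
    """Probability that a statement of this kind from this expert is true.

    theta1 = theta2 = gamma1; theta3 = gamma3; theta4 = beta1 + beta2;
    theta5 = theta6 = 1 - beta2.
    """
    if kind in (KnowledgeKind.ARC, KnowledgeKind.REVERSED_ARC):
        return acc.gamma1
    if kind is KnowledgeKind.NO_EDGE:
        return acc.gamma3
    if kind is KnowledgeKind.SOME_EDGE:
        return acc.beta1 + acc.beta2
    return 1.0 - acc.beta2


def knowledge_likelihood_explicit(kind: KnowledgeKind, state: EdgeState,
                                  acc: ExpertAccuracy) -> float:
    """P(explicit statement | true edge state) for one expert.

    Under a true arc the expert reports the correct orientation with
    probability gamma1, the reversed one with gamma2 and "no edge" with the
    residual 1 - gamma1 - gamma2.  Under true absence, "no edge" has
    probability gamma3 and the two orientations split the residual evenly.
    """
    if not kind.is_explicit:
        raise ValueError(f"{kind!r} is not an explicit kind")
    if state is EdgeState.ABSENT:
        if kind is KnowledgeKind.NO_EDGE:
            return acc.gamma3
        return (1.0 - acc.gamma3) / 2.0
    correct = KnowledgeKind.ARC if state is EdgeState.FORWARD else KnowledgeKind.REVERSED_ARC
    if kind is correct:
        return acc.gamma1
    if kind is KnowledgeKind.NO_EDGE:
        return 1.0 - acc.gamma1 - acc.gamma2
    return acc.gamma2


def knowledge_likelihood_vague(kind: KnowledgeKind, state: EdgeState,
                               acc: ExpertAccuracy) -> float:
    """P(vague statement | true edge state) for one expert.

    Under a true arc the expert reports "associated" with probability beta1,
    wrongly excludes the true direction with beta2 and excludes the false
    direction with the residual.  Under true absence the two exclusions
    split beta3 evenly and "associated" takes 1 - beta3.
    """
    if not kind.is_vague:
        raise ValueError(f"{kind!r} is not a vague kind")
    if state is EdgeState.ABSENT:
        if kind is KnowledgeKind.SOME_EDGE:
            return 1.0 - acc.beta3
        return acc.beta3 / 2.0
    if kind is KnowledgeKind.SOME_EDGE:
        return acc.beta1
    # NOT_PARENT excludes X->Y; it contradicts a FORWARD state
    wrong = KnowledgeKind.NOT_PARENT if state is EdgeState.FORWARD else KnowledgeKind.NOT_CHILD
    if kind is wrong:
        return acc.beta2
    return 1.0 - acc.beta1 - acc.beta2


@dataclass
class FusedKnowledge:
    """Fused multi-expert knowledge, partitioned by what it asserts.

    * ``ce`` -- ordered pairs (X, Y) asserting the arc X -> Y (fused explicit
      existence knowledge; a fused ``<-`` is stored on the reversed pair);
    * ``ca`` -- unordered pairs asserting no edge (fused explicit absence);
    * ``ie`` -- unordered pairs asserting an edge of unknown direction
      (fused vague existence);
    * ``ia`` -- ordered pairs (X, Y) asserting "X is not a parent of Y"
      (fused vague absence; a fused ``</-`` on (X, Y) is stored as ``-/>``
      on (Y, X)).

    Each mapping carries the fused credibility theta of the pair; the union
    of the four mappings is the credibility set B.
    """

    ce: dict[tuple[str, str], float] = field(default_factory=dict)
    ca: dict[tuple[str, str], float] = field(default_factory=dict)
    ie: dict[tuple[str, str], float] = field(default_factory=dict)
    ia: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def credibility_set(self) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        for part in (self.ce, self.ca, self.ie, self.ia):
            out.update(part)
        return out

    def __len__(self) -> int:
        return len(self.ce) + len(self.ca) + len(self.ie) + len(self.ia)


def fuse_pair(items: Sequence[KnowledgeItem],
              accuracies: Mapping[int, ExpertAccuracy],
              rng: np.random.Generator) -> tuple[KnowledgeKind, float]:
    """Fuse all statements about one node pair into a single (kind, theta).

    Experts are grouped by kind; each kind's credibilities are summed and
    normalized into selection probabilities P_l; one kind is drawn by
    roulette over the six subintervals of [0, 1]; the fused credibility is
    the arithmetic mean of the selected kind's supporters.

    All items must address the same unordered pair; items given on the
    reversed pair are reoriented onto the first item's ordering first.
    """
    if not items:
        raise ValueError("fuse_pair requires at least one knowledge item")
    x, y = items[0].x, items[0].y
    items = [it.reoriented(x, y) for it in items]

    sums = np.zeros(6)
    thetas: dict[int, list[float]] = {k: [] for k in range(1, 7)}
    for it in items:
        theta = credibility(it.kind, accuracies[it.expert_id])
        sums[it.kind.value - 1] += theta
        thetas[it.kind.value].append(theta)
    total = sums.sum()
    if total <= 0.0:
        # all supporters have zero credibility; fall back to a uniform draw
        probs = np.full(6, 1.0 / 6.0)
    else:
        probs = sums / total
    u = float(rng.random())
    chosen = int(np.searchsorted(np.cumsum(probs), u, side="right"))
    chosen = min(chosen, 5)
    # the drawn subinterval can have zero width only at the numeric boundary;
    # fall back to the first supported kind in that degenerate case
    if not thetas[chosen + 1]:
        chosen = next(k - 1 for k in range(1, 7) if thetas[k])
    kind = KnowledgeKind(chosen + 1)
    theta = float(np.mean(thetas[kind.value]))
    return kind, theta


def fuse_all(items: Iterable[KnowledgeItem],
             accuracies: Mapping[int, ExpertAccuracy],
             rng: np.random.Generator,
             variables: Sequence[str] | None = None) -> FusedKnowledge:
    """Fuse every node pair's statements and route them into CE'/CA'/IE'/IA'.

    Pairs are canonicalized to the given variable order (or, failing that,
    lexicographically) and processed in node-pair order so that runs are
    reproducible under a fixed generator.
    """
    order = {name: i for i, name in enumerate(variables)} if variables else None

    def canon(x: str, y: str) -> tuple[str, str]:
        if order is not None:
            return (x, y) if order[x] < order[y] else (y, x)
        return (x, y) if x < y else (y, x)

    grouped: dict[tuple[str, str], list[KnowledgeItem]] = {}
    for it in items:
        pair = canon(it.x, it.y)
        grouped.setdefault(pair, []).append(it.reoriented(*pair))

    if order is not None:
        names = list(variables)  # type: ignore[arg-type]
        pair_order = [(names[i], names[j]) for i, j in enumerate_node_pairs(len(names))]
        ordered_pairs = [p for p in pair_order if p in grouped]
        ordered_pairs += [p for p in grouped if p not in set(pair_order)]
    else:
        ordered_pairs = sorted(grouped)

    fused = FusedKnowledge()
    for (x, y) in ordered_pairs:
        kind, theta = fuse_pair(grouped[(x, y)], accuracies, rng)
        if kind is KnowledgeKind.ARC:
            fused.ce[(x, y)] = theta
        elif kind is KnowledgeKind.REVERSED_ARC:
            fused.ce[(y, x)] = theta
        elif kind is KnowledgeKind.NO_EDGE:
            fused.ca[(x, y)] = theta
        elif kind is KnowledgeKind.SOME_EDGE:
            fused.ie[(x, y)] = theta
        elif kind is KnowledgeKind.NOT_PARENT:
            fused.ia[(x, y)] = theta
        else:  # NOT_CHILD on (x, y) == NOT_PARENT on (y, x)
            fused.ia[(y, x)] = theta
    return fused


def simulate_experts(truth: DirectedAcyclicStructure,
                     accuracies: Sequence[ExpertAccuracy] | Mapping[int, ExpertAccuracy],
                     v: float,
                     case: str,
                     rng: np.random.Generator) -> list[KnowledgeItem]:
    """Generate expert reports about a fraction ``v`` of all node pairs.

    ``round(v * n_pairs)`` pairs (ties up) are chosen uniformly without
    replacement; every expert reports on every chosen pair.  Reports are
    drawn from the explicit tree (``case='explicit'``), the vague tree
    (``case='vague'``) or, per item, a fair coin between the two
    (``case='ev'``), conditioned on the pair's true edge state.
    """
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"coverage fraction v must lie in [0, 1], got {v}")
    if case not in ("explicit", "vague", "ev"):
        raise ValueError(f"unknown knowledge case {case!r}")
    if isinstance(accuracies, Mapping):
        acc_map = dict(accuracies)
    else:
        acc_map = {i + 1: a for i, a in enumerate(accuracies)}
    if not acc_map:
        raise ValueError("at least one expert is required")

    names = truth.names
    pairs = [(names[i], names[j]) for i, j in enumerate_node_pairs(len(names))]
    n_select = int(np.floor(v * len(pairs) + 0.5))
    if n_select == 0:
        return []
    chosen_idx = rng.choice(len(pairs), size=n_select, replace=False)
    chosen = [pairs[i] for i in sorted(chosen_idx)]

    items: list[KnowledgeItem] = []
    for (x, y) in chosen:
        state = truth.pair_state(x, y)
        for expert_id in sorted(acc_map):
            acc = acc_map[expert_id]
            if case == "explicit":
                explicit = True
            elif case == "vague":
                explicit = False
            else:
                explicit = bool(rng.random() < 0.5)
            kinds = EXPLICIT_KINDS if explicit else VAGUE_KINDS
            tree = knowledge_likelihood_explicit if explicit else knowledge_likelihood_vague
            probs = np.array([tree(k, state, acc) for k in kinds])
            u = float(rng.random())
            k = int(np.searchsorted(np.cumsum(probs), u, side="right"))
            k = min(k, len(kinds) - 1)
            items.append(KnowledgeItem(expert_id, x, y, kinds[k]))
    return items


# ---------------------------------------------------------------------------
# file formats and the packaged accuracy table
# ---------------------------------------------------------------------------

def write_knowledge_csv(items: Iterable[KnowledgeItem], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["expert_id", "var_x", "var_y", "kind"])
        for it in items:
            writer.writerow([it.expert_id, it.x, it.y, it.kind.value])


def read_knowledge_csv(path: str | Path) -> list[KnowledgeItem]:
    items = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            items.append(KnowledgeItem(int(row["expert_id"]), row["var_x"],
                                       row["var_y"], KnowledgeKind(int(row["kind"]))))
    return items


def write_accuracies_csv(accuracies: Mapping[int, ExpertAccuracy],
                         path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["expert_id", "gamma1", "gamma2", "gamma3",
                         "beta1", "beta2", "beta3"])
        for expert_id in sorted(accuracies):
            a = accuracies[expert_id]
            writer.writerow([expert_id, a.gamma1, a.gamma2, a.gamma3,
                             a.beta1, a.beta2, a.beta3])


def read_accuracies_csv(path: str | Path) -> dict[int, ExpertAccuracy]:
    out: dict[int, ExpertAccuracy] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[int(row["expert_id"])] = ExpertAccuracy(
                float(row["gamma1"]), float(row["gamma2"]), float(row["gamma3"]),
                float(row["beta1"]), float(row["beta2"]), float(row["beta3"]))
    return out


def default_accuracies() -> dict[int, ExpertAccuracy]:
    """The packaged ten-expert accuracy table used by the benchmark protocol."""
    ref = resources.files("hybridbn").joinpath("data/expert_accuracies.csv")
    with resources.as_file(ref) as path:
        return read_accuracies_csv(path)
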