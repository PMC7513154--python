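"""Structural comparison metrics and run-level summaries.

The learned DAG is compared with the reference DAG per unordered pair:
an arc of the reference recovered with the same direction is *correct* (C),
with the opposite direction *inverted* (I), and missing *deleted* (D); an
arc absent from the reference but present in the learned graph is *added*
(A).  The structural Hamming distance is SHD = A + D + I.  Over repeated
runs, MR (mean result) averages each metric and BR (best result) takes the
minimum SHD and the maximum score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import DirectedAcyclicStructure, EdgeState, enumerate_node_pairs

__all__ = ["StructuralDiff", "structural_diff", "RunSummary", "summarize_runs"]


@dataclass(frozen=True)
class StructuralDiff:
    """Arc-level differences between a learned and a reference structure."""

    added: int
    deleted: int
    inverted: int
    correct: int

    @property
    def shd(self) -> int:
        return self.added + self.deleted + self.inverted


def structural_diff(learned: DirectedAcyclicStructure,
                    truth: DirectedAcyclicStructure) -> StructuralDiff:
    """Count added, deleted, inverted and correct arcs against the reference."""
    if tuple(v.name for v in learned.variables) != tuple(v.name for v in truth.variables):
        raise ValueError("learned and reference structures have different variables")
    names = truth.names
    added = deleted = inverted = correct = 0
    for i, j in enumerate_node_pairs(len(names)):
        t = truth.pair_state(names[i], names[j])
        l = learned.pair_state(names[i], names[j])
        if t is EdgeState.ABSENT:
            if l is not EdgeState.ABSENT:
                added += 1
        elif l is EdgeState.ABSENT:
            deleted += 1
        elif l is t:
            correct += 1
        else:
            inverted += 1
    return StructuralDiff(added, deleted, inverted, correct)


@dataclass(frozen=True)
class RunSummary:
    """MR/BR summary of repeated runs."""

    n_runs: int
    mr_shd: float
    mr_added: float
    mr_deleted: float
    mr_inverted: float
    mr_correct: float
    br_shd: int
    mr_score: float | None = None
    br_score: float | None = None

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        out = {
            "MR_SHD": round(self.mr_shd, ndigits),
            "MR_A": round(self.mr_added, ndigits),
            "MR_D": round(self.mr_deleted, ndigits),
            "MR_I": round(self.mr_inverted, ndigits),
            "MR_C": round(self.mr_correct, ndigits),
            "BR_SHD": self.br_shd,
        }
        if self.mr_score is not None:
            out["MR_score"] = round(self.mr_score, ndigits)
        if self.br_score is not None:
            out["BR_score"] = round(self.br_score, ndigits)
        return out


def summarize_runs(diffs: Sequence[StructuralDiff],
                   scores: Sequence[float] | None = None) -> RunSummary:
    """Arithmetic means (MR) plus best results (minimum SHD, maximum score)."""
    if not diffs:
        raise ValueError("at least one run is required")
    n = len(diffs)
    if scores is not None and len(scores) != n:
        raise ValueError("scores must align with diffs")
    return RunSummary(
        n_runs=n,
        mr_shd=sum(d.shd for d in diffs) / n,
        mr_added=sum(d.added for d in diffs) / n,
        mr_deleted=sum(d.deleted for d in diffs) / n,
        mr_inverted=sum(d.inverted for d in diffs) / n,
        mr_correct=sum(d.correct for d in diffs) / n,
        br_shd=min(d.shd for d in diffs),
        mr_score=(sum(scores) / n) if scores is not None else None,
        br_score=max(scores) if scores is not None else None,
    )
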