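"""Simulate heterogeneous experts and fuse their conflicting statements.

Each expert reports one of six statement kinds per node pair (arc ->, arc
<-, no edge, "associated", "X not a parent of Y", "Y not a parent of X");
the first three are explicit, the last three vague.  Every statement gets a
credibility theta from the expert's accuracy parameters, and conflicting
statements about a pair are fused by roulette selection proportional to
summed credibility.
"""

import numpy as np

import hybridbn as hb

truth = hb.load_fixture("fig1")          # A->B, B->C, B->D
accuracies = hb.default_accuracies()     # the packaged ten-expert table
rng = np.random.default_rng(7)

items = hb.simulate_experts(truth, accuracies, v=1.0, case="ev", rng=rng)
print(f"{len(items)} statements from {len(accuracies)} experts "
      f"on {len(items) // len(accuracies)} node pairs")

acc1 = accuracies[1]
print(f"expert 1 credibilities: arc={hb.credibility(hb.KnowledgeKind.ARC, acc1):.2f} "
      f"associated={hb.credibility(hb.KnowledgeKind.SOME_EDGE, acc1):.2f} "
      f"not-parent={hb.credibility(hb.KnowledgeKind.NOT_PARENT, acc1):.2f}")

fused = hb.fuse_all(items, accuracies, rng, variables=truth.names)
print(f"\nfused knowledge ({len(fused)} pairs):")
print(f"  CE' (arc asserted):        {sorted(fused.ce)}")
print(f"  CA' (no edge asserted):    {sorted(fused.ca)}")
print(f"  IE' (edge, direction open):{sorted(fused.ie)}")
print(f"  IA' (one direction ruled out): {sorted(fused.ia)}")
print("theta values are the mean credibility of each fused statement's "
      "supporters; stage 1 fires its add/delete rules with these probabilities.")
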