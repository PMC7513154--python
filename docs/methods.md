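# Methods

This note records the model, the numerical and design choices, and what the
simulation harness does and does not establish.

## Model and pipeline

The learner targets a discrete Bayesian network `BN = (G, ρ)`: a DAG `G`
over variables with arities `r_i`, and per-node CPTs `ρ_i` with one row per
parent configuration (`q_i = prod of parent arities` rows, mixed-radix row
order with the first-listed parent most significant).  The joint factorizes
as `P(X1..Xn) = prod_i P(Xi | pa(Xi))`.

Learning proceeds in two stages.

**Stage 1 (constraint-based seed).**  For every unordered node pair a
dependence score is computed (below); pairs above a threshold `tau` become
undirected edges, which are then pruned by G² conditional-independence
tests over conditioning subsets of the endpoints' neighbours (sizes 0 to
`max_cond`).  Unshielded triples x−z−y whose smallest separating set
excludes z are oriented as v-structures x→z←y (first orientation wins on
conflict).  Fused expert knowledge edits the graph via four rules, each
consuming exactly one uniform draw and firing iff the draw falls in the
open interval (0, θ):

1. vague "associated" adds the undirected edge (before orientation);
2. vague "X not a parent of Y" deletes the directed arc ⟨X,Y⟩ (after
   orientation; an undirected edge is left alone — the rule asserts only
   the ordered parenthood);
3. explicit "no edge" deletes the undirected edge (before orientation);
4. explicit arc knowledge inserts ⟨X,Y⟩ (after orientation), replacing an
   undirected edge or an opposite arc; insertions that would close a
   directed cycle are skipped and logged.

Within each phase vague rules run before explicit rules and pairs are
processed in node-pair order, so a run is fully reproducible from its seed.

**Stage 2 (score-based search).**  Binary PSO over adjacency matrices,
seeded half from random acyclic completions of the stage-1 structure and
half from sparse random digraphs, maximizes a decomposable score; every
position is repaired to acyclicity (removing the largest-pair-index arc on
each detected cycle).  The swarm's global best is then polished by
steepest-ascent single-arc moves (add / delete / reverse) to a local
optimum.  The polish exists because sigmoid-transfer BPSO is strong at
coarse exploration but weak at the last few bits: on 8-node problems the
raw swarm reliably stalled several nats below score optima that the
combined search reaches.

**Scores.**  `LL = Σ m_ijk ln(m_ijk/m_ij)`; `BIC = LL − (ln N)/2 · Σ
q_i(r_i−1)`; BDeu with hyperparameters `ess/(q_i r_i)`.  The
explicit-vague BIC adds, per expert and per statement, the log probability
of that statement given the candidate's edge state on the pair, with vague
terms weighted by `k = 0.5` (each vague statement leaves two edge states
open).  Statement likelihoods follow two three-leaf decision trees:

| true state | P(→) | P(←) | P(↮) |   | P(−) | P(↛) | P(↚) |
|------------|------|------|------|---|------|------|------|
| → | γ1 | γ2 | 1−γ1−γ2 | | β1 | β2 | 1−β1−β2 |
| ← | γ2 | γ1 | 1−γ1−γ2 | | β1 | 1−β1−β2 | β2 |
| ↮ | (1−γ3)/2 | (1−γ3)/2 | γ3 | | 1−β3 | β3/2 | β3/2 |

In the vague tree the β2 (reverse-orientation error) mass goes to the
exclusion that contradicts the true direction; this is the only assignment
consistent with the credibility identities θ4 = β1+β2 and θ5 = θ6 = 1−β2
and with normalization.  Statement probabilities of zero are floored at
1e−12 inside the log so that search over contradicting structures stays
finite.  Scoring uses the raw per-expert statements; fusion feeds stage 1
only.

**Fusion.**  Statements about a pair are grouped by kind; the six kinds'
summed credibilities are normalized into selection probabilities and one
kind is drawn by roulette; its credibility is the arithmetic mean over its
supporters.  "Y is not a parent of X" on (X,Y) is canonicalized to "not a
parent" on (Y,X), and a fused "←" to an arc on the reversed pair, so the
fused sets hold only ordered "is/is not a parent" assertions.

## Dependence score

The stage-1 screen is a normalized maximal-information score for
categorical vectors: over every grid formed by merging adjacent categories
of each axis (total cells capped at n^0.6, the native category grid always
admissible), the maximum of `I(binned X; binned Y) / min(H_bins(X),
H_bins(Y))`.  Normalizing by the minimum bin entropy rather than
`log min(k_x, k_y)` makes the score exactly 1 for identical (or bijectively
relabelled) variables even when the marginal is non-uniform — ties make an
equitable partition unattainable for discrete data — while keeping the
score in [0,1], symmetric, and near 0 under independence.  Constant vectors
score 0.  Default threshold `tau = 0.1`.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `tau` | 0.1 | dependence-screen threshold (unitless score in [0,1]) |
| `alpha` | 0.05 | CI-test significance level |
| `max_cond` | 3 | largest conditioning-set size |
| `k` | 0.5 | vague-knowledge weight in the EVBIC |
| `ess` | 1.0 | BDeu equivalent sample size |
| swarm | 30 particles, 200 iterations, w=0.8, c1=c2=2, v_max=6 | BPSO settings |
| `concentration` | 0.5 | Dirichlet parameter of generated CPT rows |

`v_max` deserves a note: the sigmoid transfer floors every bit's flip
probability at `sigmoid(−v_max)` per iteration.  At 4 that floor is 1.8%,
which on networks with tens of node pairs keeps about one random defect in
every proposal and prevents convergence; 6 (floor 0.25%) lets the swarm
settle while the velocity dynamics still escape local optima.

## Simulation harness

`random_cpts` equips a structure fixture with rows drawn from a symmetric
Dirichlet; concentration 0.5 yields the skewed, fairly deterministic rows
typical of diagnostic networks and gives the data a clear signal.
`simulate_experts` picks `round(v · n(n−1)/2)` pairs uniformly; every
expert reports on every selected pair, sampling from the explicit tree, the
vague tree, or (case `ev`) a fair per-item coin between them, conditioned
on the true edge state.  The packaged ten-expert accuracy table (γ1 from
0.65 to 0.8, γ2 from 0.11 to 0.2, γ3 from 0.7 to 0.82, with β set equal to
γ) represents moderately reliable, heterogeneous experts.

The experiment driver pairs dataset *i* with knowledge set *i* (a paired
design, so case comparisons share data), derives all per-replicate seeds
from one master seed, and reports MR (means over replicates, tabulated to
one decimal) and BR (minimum SHD, maximum score).  Structural metrics
compare raw DAGs: per reference arc, correct / inverted / deleted; per
non-adjacent reference pair, added; SHD = A + D + I.

What passing tests show — and what they do not: the harness demonstrates
the method's behaviour under *its own* generative assumptions (faithful
forward-sampled data, experts whose errors follow the stated trees,
accuracies known exactly).  Real elicited knowledge has correlated errors
across experts and pairs, accuracies are estimated not known, and real
systems need not be faithful to any DAG; none of that is exercised here.
Benchmark CPTs are generated, not the (unpublished) literature tables, so
absolute benchmark numbers are comparable only in ordering and rough
magnitude, not digit-for-digit.

## Numerical choices and degenerate inputs

* Probabilities are validated to sum to 1 within 1e−9; network file
  round-trips preserve CPTs to 1e−12 (full-precision text output).
* CI tests: zero conditioning strata contribute nothing; zero cells
  contribute zero to G²; degrees of freedom are
  `(r_x−1)(r_y−1)·prod r_z` regardless of empty cells.
* Rule draws test the open interval, so θ = 0 never fires and θ = 1 fires
  almost surely; every statement consumes its draw even when the action is
  a no-op, keeping streams aligned across configurations.
* Ties: equal swarm scores keep the first-found particle; conflicting
  v-structure orientations keep the first; fusion roulette falls back to
  the first supported kind at the numeric boundary.
* Topological order breaks ties by variable index, so sampling consumes
  randomness in a platform- and hash-seed-independent order.
* Problem sizes in the shipped tests and the acceptance script (Asia at
  2000 samples, ten replicates, default swarm) were chosen so the whole
  protocol re-runs in well under a minute on one CPU while leaving the
  knowledge-case ordering clearly resolved.

## Known limitations

* Orientation propagation stops at v-structures (no Meek rules); the
  completion of remaining undirected edges is random, by design.
* The credibility identities (θ4 = β1+β2, θ5 = 1−β2) are taken as given;
  they are not posterior probabilities under an explicit prior.
* Vague knowledge alone can never orient an edge — with only vague
  statements the direction falls back to the data's equivalence-class tie.
* Alarm-scale search (37 nodes, 666 pairs) works but needs materially more
  swarm effort than the defaults tuned for Asia-scale problems.
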