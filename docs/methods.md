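# Methods

This note records the model, the parameter choices, the simulator's
scope, and the numerical decisions behind `netq`, in the order a reader
meets them in the code.

## The CRF querying model

Querying G = (V, E) in G′ = (V′, E′) is a labeling problem over
V′ ∪ {GAP}. The probability of a labeling Y factorizes over query nodes
and query edges,

    Pr(Y|G) ∝ ∏_i f_N(y_i) · ∏_(i,j)∈E f_E(y_i, y_j),

with f_N(y_i) = S(v_i, y_i) and f_E(y_i, y_j) = ½(S(v_i,y_i) +
S(v_j,y_j)) · W(y_i, y_j). The normalization Z(G) is never computed:
only the MAP labeling is needed and Z shifts every labeling's log-score
equally (property-tested).

**The edge compatibility W.** The model framework only requires W ≥ 0;
this package uses a distance-decay form

    W(y_i, y_j) = decay^(d−1)   for target distance 1 ≤ d ≤ dmax,
                  floor_eps      otherwise or when y_i = y_j,
                  1              when either label is GAP.

Defaults: dmax = 2, decay = 0.5. The decay tolerates single node
insertions/deletions in the target (an edge may map onto a two-hop
path), which is exactly what the EAC(k) evaluation curve measures. The
same-label penalty discourages adjacent query nodes from collapsing
onto one target node. Whether to admit two-hop images at all is exposed
(`--dmax 1` restores strict adjacency).

**GAP.** Unmatched is a first-class outcome: GAP is a real label with
constant potential `gap_score` (default 0.01) and neutral W, and a GAP
endpoint contributes `gap_score` to the edge feature's similarity
average. The duplication benchmark *requires* gaps: a duplicate's
correct fate is to stay unmatched.

**Candidate pruning.** Each query node's label domain is its `top_k`
(default 10) positively-scored targets plus GAP. Similarity files are
sparse in practice (BLAST hits), so this loses nothing while keeping
the grounded model linear in |V|.

**Numerical floor.** All potentials are floored at `floor_eps = 1e-6`
so log-space scores stay finite. The floor is a strong penalty: one
query edge whose endpoint images are unreachable within dmax costs
log(1e-6) ≈ −13.8, more than a dozen conserved edges gain. This is
deliberate — a hard structural veto — but it makes sparse targets
punishing; see Limitations.

## Inference

Forest queries are solved exactly by max-product dynamic programming
(root each tree at its lexicographically smallest node, upward max
messages with argmax pointers, downward decode). Cyclic queries use
damped loopy max-product belief propagation (damping 0.5, at most 100
fixed-order sweeps, convergence at message change < 1e-9), decoded by
per-node max-marginals. Exactness on forests is enforced by a
brute-force enumeration oracle in the tests (200 random instances);
loopy decoding is validated on cyclic queries in the strong-signal
regime where the optimum leads the runner-up by more than 1%. Every
tie — candidate ranking, message argmax, decoding — breaks
lexicographically on node identifier, making runs bit-reproducible
without any randomness in inference.

## Iterative bi-directional alignment

One query is asymmetric and possibly many-to-one. Each alignment round
queries both directions, takes the reciprocal pairs {(u, v): fwd(u)=v,
bwd(v)=u} (necessarily one-to-one), and clamps them: S(u,v) ← boost
(default 1 + max observed score) while the rest of row u and column v
is zeroed. Clamped nodes thereby vanish from all other candidate
domains, shrinking the problem each round. The loop stops when a round
fixes nothing new; a `max_rounds` cap (default 20) guards against
pathological oscillation, which was never observed. Only accumulated
fixed pairs are returned — non-reciprocal assignments of the final
round are discarded, since reciprocity is what guarantees one-to-one,
direction-symmetric output. Inference restarts from the updated model
each round rather than warm-starting; with lexicographic tie-breaking
this makes the aligner exactly symmetric in its two arguments
(property-tested).

**Best-hit baselines.** `best_hit_query` maps each node to its highest
similarity score; `best_hit_align` wraps it in the same loop. A tied
maximum means the hits are indistinguishable on similarity alone, and
the node is left unmatched by default (`ties="drop"`). This mirrors
best-hit lists that report all tied hits, none of which survives
one-to-one extraction — and it is what makes the baseline provably
blind to duplicates (below). A `ties="lexicographic"` policy exists for
deterministic toy constructions.

## The duplication simulator

One duplication event: pick v uniformly from the not-yet-affected set
R, copy its interaction pattern to v′, remove round(p1·deg) of v′'s
edges and round(p2·deg) of v's (uniformly, independently), then retire
{v} ∪ N(v) from R. Events repeat until N duplications or R empties —
so duplications never hit a node twice or two adjacent nodes, keeping
events uncorrelated. Finally round(p3·|E′|) edges are removed from the
whole network. Choices the model statement leaves open:

* "remove a fraction p" uses Python's round-half-even on p·degree;
* v–v′ itself is not linked (duplication copies the pattern only); a
  `link_duplicate` flag models heterodimerizing duplicates instead;
* the background loss (step 6) draws uniformly from the final edge
  multiset, so it may further thin already-thinned copies;
* duplicate identifiers are `<base>__dup` for debuggability; ground
  truth (origin map, D, A, R, removal tallies) is carried explicitly.

The synthetic similarity assigns S(u, w) = 1 wherever origin(w) = u:
every duplicated base node has two perfect hits (itself and its copy),
and nothing else distinguishes them — the deliberate ambiguity the
aligner must resolve structurally. Optional uniform noise entries
(`noise_pairs`, `background`) can emulate spurious cross-hits; the
default is noiseless.

**What this emulates and what it does not.** The simulator reproduces
the one feature that defeats sequence-only alignment — duplicate
ambiguity — on top of an arbitrary base topology. It does not model
sequence divergence after duplication, structure-dependent loss rates,
paralog families (real BLAST rows have many weak cross-hits), or
measurement noise other than uniform edge loss. Consequently, passing
benchmarks here show that structural evidence resolves duplications
under controlled loss rates; they do not certify performance on real
cross-species data, where node similarity is far denser and dirtier.

## Evaluation measures

Structural: MP = |pairs|; EC = 100 · conserved / denominator, where the
default denominator is query edges with both endpoints matched (fair
for partial mappings) and `all_edges` divides by |E| of the query
network instead; EAC(k) relaxes "conserved" to images within target
distance k (EAC(1) ≡ EC, enforced by tests); LCCS is the largest
component of the graph on matched pairs with edges conserved in both
networks (ties by edge count, then lexicographic).

Biological: SGO(k) = % of matched pairs sharing ≥ k GO terms, domains
pooled. GO coverage restricts to one domain at term depth ≥ 3: among
pairs where both nodes carry such a term, the % sharing one. PAC scores
a hit pathway P as 100 · 2·(within-pathway pairs) / (|P_A| + |P_B|) and
averages over hit pathways; HP counts them. OP counts matched pairs in
a supplied ortholog list. GO coverage and PAC are this package's
reconstructions of measures whose original formulas live in prior
benchmarking literature; each is isolated in a single function for easy
revision. GO depth and domain arrive as input columns — ontology
parsing is out of scope. Degenerate denominators (no matched pairs, no
eligible pairs, no hit pathways) report 0, with a warning where it is
surprising.

Duplication-aware accuracy: a duplicated node v is correct iff it maps
to itself AND its copy is the image of nothing (aligned with gap);
overall accuracy additionally requires every non-duplicated node to map
to itself.

## Benchmark scale

The simulated benchmark in the tests and in `scripts/acceptance.py`
runs on a seeded Barabási–Albert base of 500 nodes / ~1500 edges with
N = 25 duplications, (p1, p2, p3) = (0.2, 0.1, 0.005) and 10
replicates — the package's desk-scale stand-in for the yeast PPI
network (2390 proteins, 16127 interactions, N = 100) used in the
original comparison. At this scale a full run completes in about two
minutes on one CPU.

## Known limitations

* On the 500-node scale-free surrogate the CRF aligner's duplicated-node
  accuracy averages ≈ 90–92%, a few points below the published
  full-scale figure. Two effects, both verified to be genuine MAP optima
  rather than inference errors, account for the gap: for degrees 6–7,
  round(p1·deg) = round(p2·deg), so original and copy lose equally many
  edges and the distance-decay W must break a near-tie; and a lost edge
  whose images sit beyond dmax triggers the floor veto, occasionally
  sending a high-degree node to GAP. Both effects shrink on denser
  networks.
* With noiseless 0/1 similarity the one-shot query already produces no
  target collisions, so the iterative strategy has little left to
  repair and the aligner's advantage over plain querying is small; the
  advantage grows with ambiguous (noisy, paralog-rich) similarity.
* Loopy BP carries no global optimality guarantee on cyclic queries;
  weak-signal instances can decode to local optima.
* Networks are undirected and unweighted throughout; directed
  (metabolic, regulatory) graphs and edge confidences are out of scope,
  as are multi-network alignment and many-to-many mappings.
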