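# Methods

## Model

SIWR treats each edge of an undirected, unweighted simple graph as an event
whose probability is the reciprocal degree product of its endpoints,
`P(v_i, v_j) = 1/(d_i d_j)`, and weights the edge by the event's
self-information `W(v_i, v_j) = log2(d_i d_j)` bits. The weight is symmetric
and nonnegative, vanishing only for an edge joining two degree-1 nodes. A
node's strength `W(v_i)` sums its incident edge weights; its score is the
base-2 Shannon entropy of the strengths of its closed neighborhood
`Γ(v_i) = N(v_i) ∪ {v_i}`, normalized by the neighborhood strength
`W⁺(v_i)`. Two standard entropy facts shape the score and are exercised as
test invariants: for a fixed neighborhood size the entropy is maximal when
the strength distribution is uniform (bounded by `log2(|Γ|)`), and appending
an event of positive mass never decreases the raw self-information sum. A
node therefore scores highly when it has many neighbors whose local edge
information is substantial and evenly spread — degree alone does not decide
the order (in the bundled 6-node example the two degree-3 nodes separate
cleanly).

All SIWR quantities use base-2 logarithms; the mutual-information baseline is
the one natural-log quantity, matching its usual definition.

## Degenerate inputs

The entropy normalization is undefined when `W⁺(v_i) = 0`: isolated nodes,
and components consisting of a single edge between two degree-1 nodes (every
incident weight is `log2(1) = 0`). Such nodes are assigned score 0 — the
infimum of the score — and a warning is logged, preserving totality of the
ranking without inventing information. Rankings place them last.

## Ranking and ties

Nodes are sorted by non-increasing score into dense order groups
(1..#groups). Scores within an absolute tolerance of `1e-10` are treated as
tied: structurally interchangeable nodes have exactly equal entropies in
exact arithmetic, and the tolerance keeps them tied under floating-point
summation-order noise. Within a tied group nodes are listed by label
(numeric labels numerically, otherwise lexically), making output
deterministic. This matters for the monotonicity index: breaking a genuine
symmetry tie through numerical noise would overstate `M(R)`. On the Zachary
karate-club network, for example, the entropy ranking leaves 13 tied pairs,
all between automorphic nodes, giving `M = (1 − 13/561)² = 0.9542`; a run
that split one such pair would report 0.9577.

## Baselines

- **DC** — degree. **MI** — `Σ_{j∈N(i)} ln(d_i d_j)`, zero for non-adjacent
  pairs.
- **CC** — `(n−1)/Σ_{j≠i} d(i,j)` with BFS hop counts and the convention
  that unreachable pairs contribute distance 0 (a fully isolated node scores
  0). The convention is part of the method definition; note it *inflates*
  closeness on disconnected graphs, since missing paths are counted as
  distance 0 rather than ∞.
- **EC** — principal eigenvector of the adjacency matrix, L2-normalized,
  nonnegative. Computed by power iteration from the uniform vector with a
  `1e-12` successive-iterate tolerance and a 100,000-iteration cap; the
  iteration runs on `A + I`, which has the same eigenvectors but a strictly
  dominant principal eigenvalue, so bipartite spectra (±λ pairs) do not
  oscillate. Convergence failure raises rather than returning a stale
  iterate.
- **KS** — iterative peeling at degree thresholds 1, 2, …, cascading within
  each stage; the label is the threshold at removal (the standard core
  number, with isolated nodes folded into shell 1 so labels stay positive).
- **IKS** — each round removes *all* nodes at the current minimum residual
  degree, and the label is the round counter, which increments every round
  regardless of the degree value; this refines the KS shells (a KS run never
  distinguishes more levels than IKS on the same graph, an invariant the
  tests check).

## Evaluation protocols

**Monotonicity** `M(R) = (1 − Σ_r n_r(n_r−1)/2 ÷ [n(n−1)/2])²` over order
group sizes `n_r`; 1 when all orders are distinct, 0 when all nodes tie.
**CCDF** of order occupancy, `CCDF(r) = (n − Σ_{i≤r} n_i)/n`, non-increasing
with terminal value 0; a smooth decay means fine discrimination.

**SIR spreading.** Discrete-time synchronous epidemics: each step, every
infected node independently infects each susceptible neighbor with
probability `β`, then recovers with probability `r` (default 1: one
infectious step). A run ends when no infected nodes remain; the propagation
ability of a seed set is the mean over `n_ite` repetitions of the fraction of
nodes ever infected, seeds and recovered included. The default
`β = 1/(⟨d⟩−1)` places the experiment near the epidemic threshold of the
mean-field approximation; it is clamped to 1 (with a warning) when
`⟨d⟩ < 2` and undefined for `⟨d⟩ ≤ 1`. Seed sets are the top-k of a ranking
(label order inside ties). Defaults: `n_ite = 1000` repetitions; seed-set
sizes 2–10 for graphs up to ~1000 nodes, 10–50 beyond, at the caller's
choice. The k-shell ranking is a poor seed selector (huge top shells) and is
conventionally excluded from this comparison, though nothing prevents
running it.

**Robustness.** Each repetition removes `⌈fraction · n⌉` uniformly sampled
nodes, restricts the original ranking to the survivors with recompacted
dense orders, re-ranks the induced subgraph, and reports the fraction of
survivors whose order index changed; the change rate is the mean over `reps`
repetitions (default 100). "Position" is genuinely ambiguous between dense
order index and raw sorted index; dense order is the default — a removal
that preserves every survivor's relative standing then yields rate 0 — and
`compare="position"` exposes the stricter reading.

All stochastic procedures accept a single integer seed and are bit-for-bit
reproducible given it; per-k SIR sub-streams are spawned from that seed so
curve entries are independent.

## Synthetic data

The generators (`erdos_renyi`, `barabasi_albert`, `star`, `path`, `cycle`,
`complete`, and the fixed 6-node `toy` fixture) provide the test bed:
Erdős–Rényi graphs exercise the average case including disconnected and
bipartite-ish structures, Barabási–Albert the heavy-tailed degree
distributions real networks show, and the deterministic families carry
closed-form expectations (star seeding ability `(1+(n−1)β)/n`, complete-graph
symmetry ties, path/cycle shell traces). What they do not emulate: degree
correlations, clustering and community structure of real social networks —
the worked example and the karate-club check cover a real topology, but
passing tests on synthetic graphs alone would not certify behavior on, say,
large assortative collaboration networks.

## Numerical choices

- Exact (full-precision) arithmetic throughout the API; human-readable
  output rounds to 4 decimals. The worked example's derived table columns
  are historically tabulated by chaining printed 4-decimal values; tests
  reproduce that tabulation convention explicitly and separately bound the
  full-precision sums.
- Entropy terms with zero mass contribute 0 (`0·log 0 := 0`).
- Tie tolerance `1e-10` absolute (see above); EC tolerance `1e-12` on
  successive iterates; oracle-equivalence tests assert `1e-8`–`1e-10`
  agreement against independent brute-force implementations.
- Test problem sizes: the random-graph oracle corpus uses 50 graphs of up to
  12 nodes (small enough for dense all-pairs/eigendecomposition oracles),
  SIR closed-form checks 10,000 repetitions on an 11-node star, robustness
  checks 600 repetitions on the 6-node fixture against a hand-enumerated
  expectation.

## Limitations

Undirected, unweighted simple graphs only; directed or weighted inputs are
out of scope. The closeness convention above distorts comparisons across
graphs with different numbers of components. SIR simulation is pure Python
over adjacency arrays — fine up to a few thousand nodes and `n_ite ~ 10³`,
not tuned for million-node graphs. The edge-list reader loads the whole
graph into memory.
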