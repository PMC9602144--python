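# siwr — self-information weighted node-importance ranking

`siwr` ranks the nodes of an undirected, unweighted simple graph by how much
information their local edge structure carries. It is aimed at anyone who
needs to pick influential nodes in a network — spreaders to seed, hubs to
protect, rumor sources to block — and wants a ranking that assigns few ties
while staying cheap to compute.

## The method

Most centrality indices score a node from its neighbors alone and treat every
incident edge as interchangeable. SIWR starts from the edges instead. An edge
`(v_i, v_j)` is assigned the probability `P(v_i, v_j) = 1 / (d_i d_j)` (with
`d_i` the degree of `v_i`), so its self-information

```
W(v_i, v_j) = −log2 P(v_i, v_j) = log2(d_i d_j)      [bits]
```

becomes its weight: edges between rarely-connected nodes carry more
information. From these weights the method builds, for each node,

- the **strength** `W(v_i) = Σ_{j ∈ N(i)} W(v_i, v_j)` — summed
  self-information of incident edges;
- the **neighborhood strength** `W⁺(v_i) = Σ_{j ∈ Γ(i)} W(v_j)` over the
  closed neighborhood `Γ(v_i) = N(v_i) ∪ {v_i}`;
- the **score** `E(v_i) = −Σ_{j ∈ Γ(i)} P(v_j) log2 P(v_j)` with
  `P(v_j) = W(v_j) / W⁺(v_i)` — the Shannon entropy of the normalized
  strength distribution over the closed neighborhood.

Nodes are ranked by non-increasing `E`; scores equal within `1e-10` share a
dense order index. The package also implements the six classical baselines
the method is compared against (degree, mutual-information, closeness,
eigenvector, k-shell and improved k-shell centralities) and four evaluation
protocols: ranking monotonicity `M(R)`, the CCDF of order occupancy, SIR
spreading ability of top-k seed sets (with `β = 1/(⟨d⟩−1)`, recovery 1), and
robustness of the ranking to random node removal.

## Worked example

The bundled 6-node fixture (edges v1–v2, v1–v3, v1–v6, v2–v3, v2–v4, v4–v5):

```
$ siwr fixture --model toy --out toy.edges
$ siwr rank --input toy.edges
% method=SIWR
% node  score   order
v2      1.9309  1
v1      1.8161  2
v3      1.5579  3
v4      1.2067  4
v5      0.7567  5
v6      0.6748  6
```

v2 wins: it has the same degree as v1, but its incident edges reach into less
redundant territory (toward the pendant chain v4–v5), so its closed
neighborhood spreads strength more evenly and its entropy is higher. All six
orders are distinct, so the ranking's monotonicity is perfect:

```
$ siwr rank --input toy.edges --output toy_rank.tsv
$ siwr eval monotonicity --ranking toy_rank.tsv
1.0000
```

On a 100-node scale-free graph, the spreading ability of the top-k SIWR seeds
under the SIR protocol (each value is the mean fraction of nodes ever
infected over 1000 epidemics):

```
$ siwr fixture --model barabasi_albert --n 100 --m-attach 2 --rng-seed 7 --out ba.edges
$ siwr eval sir --input ba.edges --method siwr --seed-counts 2,4,6,8,10 --nite 1000 --rng-seed 42
% method=SIWR beta=0.342466 nite=1000
seeds   propagation_ability
2       0.4999
4       0.5154
6       0.5383
8       0.5589
10      0.5688
```

The same operations are available as a library: `siwr.read_edge_list`,
`siwr.siwr_rank`, `siwr.rank(g, "ec")`, `siwr.monotonicity`, `siwr.ccdf`,
`siwr.sir_simulate`, `siwr.robustness_change_rate`, and the graph generators
`siwr.generate(...)` / `siwr.toy_graph()`.

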