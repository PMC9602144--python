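"""Self-information weighted ranking (SIWR) of node importance in graphs.

The method scores each node of an undirected, unweighted simple graph by
first weighting every edge ``(v_i, v_j)`` with its self-information

    W(v_i, v_j) = -log2 P(v_i, v_j) = log2(d_i * d_j),

where ``d_i`` is the degree of ``v_i``, and then taking the Shannon entropy
(base 2) of the normalized strength distribution over the node's closed
neighborhood.  Nodes with higher entropy sit in locally edge-information-rich,
evenly connected surroundings and rank as more important.

The module is organised in the order the method runs:

1. graph container and edge-list I/O (KONECT-style whitespace dialect);
2. the SIWR weighting/entropy pipeline and its ranking;
3. six benchmark centralities (DC, MI, CC, EC, KS, IKS);
4. dense-order rankings and their TSV serialisation;
5. evaluation protocols: monotonicity M(R), CCDF of orders, SIR spreading,
   and robustness to random node removal;
6. fixture graphs and synthetic generators.

All logarithms in SIWR are base 2; the MI baseline uses the natural log.
"""

from __future__ import annotations

import io
import logging
import math
from collections.abc import Hashable, Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, NamedTuple, Sequence, Union

import networkx as nx
import numpy as np

__all__ = [
    "TIE_TOL",
    "Graph",
    "read_edge_list",
    "write_edge_list",
    "EdgeSelfInformation",
    "edge_self_information",
    "weight_graph",
    "node_strength",
    "neighborhood_strength",
    "node_entropy",
    "siwr_scores",
    "siwr_rank",
    "ScoreTable",
    "degree_centrality",
    "mutual_information_score",
    "closeness_centrality",
    "eigenvector_centrality",
    "k_shell",
    "improved_k_shell",
    "METHODS",
    "score",
    "RankEntry",
    "Ranking",
    "rank_from_scores",
    "rank",
    "write_ranking",
    "read_ranking",
    "monotonicity",
    "ccdf",
    "SIRConfig",
    "SIRResult",
    "default_beta",
    "sir_simulate",
    "propagation_curve",
    "robustness_change_rate",
    "toy_graph",
    "generate",
]

logger = logging.getLogger("siwr")

Node = Hashable

#: Absolute tolerance for treating two scores as tied when assigning dense
#: order indices.  Entropies of structurally equivalent nodes must compare
#: equal despite floating-point summation-order noise.
TIE_TOL = 1e-10

#: Power-iteration controls for eigenvector centrality.
EC_TOL = 1e-12
EC_MAX_ITER = 100_000


# ---------------------------------------------------------------------------
# 1. Graph container and edge-list I/O
# ---------------------------------------------------------------------------


class Graph:
    """Undirected simple graph with insertion-ordered node labels.

    Thin wrapper around :class:`networkx.Graph` that enforces the invariants
    the ranking pipeline relies on: no self-loops, no parallel edges, and a
    deterministic node order (first appearance), so that rankings and their
    tie-breaks are reproducible from the same input.
    """

    __slots__ = ("_g",)

    def __init__(self, graph: nx.Graph):
        g = nx.Graph(graph)  # copies; collapses multi-edges if any
        loops = list(nx.selfloop_edges(g))
        if loops:
            logger.warning("dropping %d self-loop(s)", len(loops))
            g.remove_edges_from(loops)
        self._g = g

    # -- construction -------------------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[Node, Node]], nodes: Iterable[Node] = ()
    ) -> "Graph":
        """Build a graph from an edge iterable.

        ``nodes`` may list extra (possibly isolated) nodes; node order is
        first appearance across ``nodes`` then ``edges``.
        """
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return cls(g)

    # -- basic queries ------------------------------------------------------

    @property
    def nodes(self) -> tuple[Node, ...]:
        return tuple(self._g.nodes)

    @property
    def n(self) -> int:
        return self._g.number_of_nodes()

    @property
    def m(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> list[tuple[Node, Node]]:
        return list(self._g.edges)

    def has_node(self, i: Node) -> bool:
        return self._g.has_node(i)

    def has_edge(self, i: Node, j: Node) -> bool:
        return self._g.has_edge(i, j)

    def _check_node(self, i: Node) -> None:
        if not self._g.has_node(i):
            raise KeyError(f"unknown node: {i!r}")

    def degree(self, i: Node) -> int:
        self._check_node(i)
        return self._g.degree[i]

    def neighbors(self, i: Node) -> set[Node]:
        self._check_node(i)
        return set(self._g[i])

    def closed_neighborhood(self, i: Node) -> set[Node]:
        """The node together with its neighbors, Γ(v_i) = N(v_i) ∪ {v_i}."""
        self._check_node(i)
        return set(self._g[i]) | {i}

    def average_degree(self) -> float:
        return 2.0 * self.m / self.n if self.n else 0.0

    def bfs_distances(self, i: Node) -> dict[Node, int]:
        """Hop counts from ``i`` to every node.

        Unreachable nodes are reported as 0 (and ``d(i, i) = 0``), the
        convention the closeness baseline is defined with.  Note this makes
        disconnected graphs look spuriously "close"; see the methods note.
        """
        self._check_node(i)
        dist = nx.single_source_shortest_path_length(self._g, i)
        return {u: dist.get(u, 0) for u in self._g.nodes}

    def adjacency_matrix(self) -> np.ndarray:
        return nx.to_numpy_array(self._g, nodelist=list(self._g.nodes))

    def subgraph(self, keep: Iterable[Node]) -> "Graph":
        """Induced subgraph on ``keep``, preserving relative node order."""
        keep = set(keep)
        for u in keep:
            self._check_node(u)
        g = nx.Graph()
        g.add_nodes_from(u for u in self._g.nodes if u in keep)
        g.add_edges_from(
            (u, v) for u, v in self._g.edges if u in keep and v in keep
        )
        return Graph(g)

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Graph(n={self.n}, m={self.m})"


def _coerce_label(token: str) -> Node:
    """Parse an edge-list token: integer if it looks like one, else string."""
    try:
        return int(token)
    except ValueError:
        return token


def read_edge_list(source: Union[str, Path, io.TextIOBase]) -> Graph:
    """Read a whitespace-separated edge list (KONECT/TSV dialect).

    Lines starting with ``%`` or ``#`` are comments; each data line holds at
    least two tokens (source, target); extra columns (weights, timestamps)
    are ignored.  Duplicate and reversed pairs collapse to one edge and
    self-loops are dropped with a warning.  Node labels map to internal order
    by first appearance, so rankings are deterministic given file order.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            return read_edge_list(fh)
    g = nx.Graph()
    n_loops = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("%") or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(f"malformed edge list line {lineno}: {raw!r}")
        u, v = _coerce_label(tokens[0]), _coerce_label(tokens[1])
        if u == v:
            n_loops += 1
            continue
        g.add_node(u)
        g.add_node(v)
        g.add_edge(u, v)
    if n_loops:
        logger.warning("dropped %d self-loop line(s) on read", n_loops)
    if g.number_of_edges() == 0:
        raise ValueError("no edges")
    return Graph(g)


def write_edge_list(g: Graph, dest: Union[str, Path, io.TextIOBase]) -> None:
    """Write ``g`` as a KONECT-style edge list (one ``u v`` pair per line)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "wt", encoding="utf-8") as fh:
            write_edge_list(g, fh)
        return
    dest.write(f"% undirected simple graph: n={g.n} m={g.m}\n")
    for u, v in g.edges():
        dest.write(f"{u} {v}\n")


# ---------------------------------------------------------------------------
# 2. SIWR: edge self-information weighting and node entropy
# ---------------------------------------------------------------------------


class EdgeSelfInformation(Mapping):
    """Per-edge self-information weights ``W(v_i, v_j) = log2(d_i d_j)``.

    A symmetric mapping keyed by node pairs: ``w[i, j] == w[j, i]``.  Weights
    are nonnegative and zero only for an edge between two degree-1 nodes.
    """

    __slots__ = ("_w", "_edges")

    def __init__(self, weights: dict[frozenset, float], edges: list[tuple[Node, Node]]):
        self._w = weights
        self._edges = edges

    def __getitem__(self, pair: tuple[Node, Node]) -> float:
        i, j = pair
        try:
            return self._w[frozenset((i, j))]
        except KeyError:
            raise KeyError(f"not an edge: ({i!r}, {j!r})") from None

    def __iter__(self):
        return iter(self._edges)

    def __len__(self) -> int:
        return len(self._edges)

    def items(self):
        return [((u, v), self._w[frozenset((u, v))]) for u, v in self._edges]


def edge_self_information(g: Graph, i: Node, j: Node) -> float:
    """Self-information (bits) of the edge ``(i, j)``: ``log2(d_i * d_j)``.

    The probability model assigns the edge mass ``1 / (d_i d_j)``, so edges
    between low-degree (rare-contact) nodes carry more information.  Defined
    only for existing edges.
    """
    if not g.has_edge(i, j):
        raise ValueError(f"not an edge: ({i!r}, {j!r})")
    return math.log2(g.degree(i) * g.degree(j))


def weight_graph(g: Graph) -> EdgeSelfInformation:
    """Weight every edge of ``g`` by its self-information (bits).

    This is the step that turns the unweighted graph into a weighted one.
    """
    if g.m == 0:
        raise ValueError("graph has no edges to weight")
    deg = {u: g.degree(u) for u in g.nodes}
    weights = {
        frozenset((u, v)): math.log2(deg[u] * deg[v]) for u, v in g.edges()
    }
    return EdgeSelfInformation(weights, g.edges())


def node_strength(g: Graph, w: EdgeSelfInformation, i: Node) -> float:
    """Strength ``W(v_i)``: summed self-information of incident edges (bits)."""
    g._check_node(i)
    return sum(w[i, j] for j in g.neighbors(i))


def neighborhood_strength(g: Graph, w: EdgeSelfInformation, i: Node) -> float:
    """Closed-neighborhood strength ``W+(v_i) = Σ_{j ∈ Γ(i)} W(v_j)`` (bits)."""
    g._check_node(i)
    return sum(node_strength(g, w, j) for j in g.closed_neighborhood(i))


def _entropy_from_strengths(strengths: Sequence[float]) -> float:
    total = sum(strengths)
    if total <= 0.0:
        return 0.0
    ent = 0.0
    for s in strengths:
        if s > 0.0:
            p = s / total
            ent -= p * math.log2(p)
    return ent


def node_entropy(g: Graph, i: Node) -> float:
    """SIWR score of ``i``: entropy of its closed-neighborhood strengths.

    The strengths of the members of Γ(v_i), normalized by ``W+(v_i)``, form a
    probability distribution; the score is its base-2 Shannon entropy.  When
    ``W+(v_i) = 0`` (isolated node, or a component that is a single edge
    between degree-1 nodes, where every incident weight is log2(1) = 0) the
    distribution is undefined; the score is 0 — the infimum — with a warning.
    """
    g._check_node(i)
    if g.m == 0:
        logger.warning("node %r has zero neighborhood strength; entropy set to 0", i)
        return 0.0
    w = weight_graph(g)
    strengths = [node_strength(g, w, j) for j in g.closed_neighborhood(i)]
    if sum(strengths) <= 0.0:
        logger.warning("node %r has zero neighborhood strength; entropy set to 0", i)
        return 0.0
    return _entropy_from_strengths(strengths)


def siwr_scores(g: Graph) -> "ScoreTable":
    """SIWR entropy scores for all nodes of ``g`` (bits)."""
    if g.n == 0:
        raise ValueError("empty graph")
    if g.m == 0:
        logger.warning("edgeless graph: all SIWR scores set to 0")
        return ScoreTable("SIWR", {u: 0.0 for u in g.nodes})
    w = weight_graph(g)
    strength = {u: node_strength(g, w, u) for u in g.nodes}
    scores: dict[Node, float] = {}
    n_degenerate = 0
    for u in g.nodes:
        vals = [strength[v] for v in g.closed_neighborhood(u)]
        if sum(vals) <= 0.0:
            n_degenerate += 1
            scores[u] = 0.0
        else:
            scores[u] = _entropy_from_strengths(vals)
    if n_degenerate:
        logger.warning(
            "%d node(s) with zero neighborhood strength scored 0", n_degenerate
        )
    return ScoreTable("SIWR", scores)


def siwr_rank(g: Graph) -> "Ranking":
    """Rank all nodes of ``g`` by SIWR entropy, highest first.

    Runs the three phases of the method: edge weight computation, node
    entropy computation, and sorting into dense order groups (ties within
    :data:`TIE_TOL` share an order index; tied nodes list by label).
    """
    return rank_from_scores(siwr_scores(g))


# ---------------------------------------------------------------------------
# 3. Benchmark centralities: DC, MI, CC, EC, KS, IKS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreTable:
    """Per-node scores for one ranking method."""

    method: str
    scores: dict[Node, float]

    def __getitem__(self, i: Node) -> float:
        return self.scores[i]


def degree_centrality(g: Graph) -> ScoreTable:
    """DC: the score of a node is its degree."""
    return ScoreTable("DC", {u: float(g.degree(u)) for u in g.nodes})


def mutual_information_score(g: Graph) -> ScoreTable:
    """MI: sum over neighbors of ``ln(d_i d_j)``; non-edges contribute 0.

    The only natural-log quantity in the package; all SIWR quantities are
    base 2.
    """
    deg = {u: g.degree(u) for u in g.nodes}
    return ScoreTable(
        "MI",
        {
            u: sum(math.log(deg[u] * deg[v]) for v in g.neighbors(u))
            for u in g.nodes
        },
    )


def closeness_centrality(g: Graph) -> ScoreTable:
    """CC: ``(n-1) / Σ_{j≠i} d(i, j)`` with unreachable distances taken as 0.

    A fully isolated node has distance sum 0 and scores 0.  The unreachable=0
    convention inflates CC on disconnected graphs (closer to 0 distance, not
    farther); it is kept because the ranking pipeline is defined with it.
    """
    if g.n < 2:
        raise ValueError("closeness centrality requires at least 2 nodes")
    scores: dict[Node, float] = {}
    for u in g.nodes:
        total = sum(g.bfs_distances(u).values())  # unreachable and self are 0
        scores[u] = (g.n - 1) / total if total > 0 else 0.0
    return ScoreTable("CC", scores)


def eigenvector_centrality(g: Graph) -> ScoreTable:
    """EC: the principal eigenvector of the adjacency matrix, L2-normalized.

    Power iteration from the uniform positive vector; converged when the L2
    difference of successive normalized iterates drops below ``EC_TOL``.
    Iterates on ``A + I`` (same eigenvectors, strictly dominant principal
    eigenvalue) so that bipartite graphs, whose spectrum pairs ±λ, do not
    oscillate.  Entries carry the nonnegative sign convention
    (Perron–Frobenius).
    """
    if g.m == 0:
        raise ValueError("eigenvector centrality requires at least one edge")
    a = g.adjacency_matrix()
    x = np.full(g.n, 1.0 / math.sqrt(g.n))
    for _ in range(EC_MAX_ITER):
        y = a @ x + x
        norm = np.linalg.norm(y)
        if norm == 0.0:
            raise ArithmeticError("power iteration collapsed to the zero vector")
        y /= norm
        if np.linalg.norm(y - x) < EC_TOL:
            x = y
            break
        x = y
    else:
        raise ArithmeticError(
            f"eigenvector centrality did not converge in {EC_MAX_ITER} iterations"
        )
    x = np.abs(x)  # nonnegative sign convention
    x /= np.linalg.norm(x)
    return ScoreTable("EC", dict(zip(g.nodes, x.tolist())))


def k_shell(g: Graph) -> ScoreTable:
    """KS: shell labels from iterative peeling at degree thresholds 1, 2, ….

    At stage ``k`` all nodes of residual degree ≤ k are removed, cascading
    within the stage, and labelled ``k``.  This equals the standard core
    number; isolated nodes (core 0) fall in the first removed shell and are
    labelled 1 so that labels are positive.
    """
    core = nx.core_number(g.to_networkx())
    return ScoreTable("KS", {u: float(max(core[u], 1)) for u in g.nodes})


def improved_k_shell(g: Graph) -> ScoreTable:
    """IKS: repeatedly remove *all* current minimum-degree nodes.

    The removal round counter increments every iteration regardless of the
    degree value removed, so the labels refine the KS shells (e.g. degree-1
    nodes re-exposed after a degree-2 round get a fresh, higher label).
    """
    residual = g.to_networkx()
    labels: dict[Node, float] = {}
    t = 0
    while residual.number_of_nodes() > 0:
        t += 1
        degrees = dict(residual.degree())
        dmin = min(degrees.values())
        batch = [u for u, d in degrees.items() if d == dmin]
        for u in batch:
            labels[u] = float(t)
        residual.remove_nodes_from(batch)
    return ScoreTable("IKS", {u: labels[u] for u in g.nodes})


METHODS: dict[str, Callable[[Graph], ScoreTable]] = {
    "siwr": siwr_scores,
    "dc": degree_centrality,
    "mi": mutual_information_score,
    "cc": closeness_centrality,
    "ec": eigenvector_centrality,
    "ks": k_shell,
    "iks": improved_k_shell,
}


def score(g: Graph, method: str) -> ScoreTable:
    """Score all nodes of ``g`` with one of the registered methods."""
    try:
        fn = METHODS[method.lower()]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(METHODS)}"
        ) from None
    return fn(g)


# ---------------------------------------------------------------------------
# 4. Rankings: dense order indices and TSV serialisation
# ---------------------------------------------------------------------------


class RankEntry(NamedTuple):
    node: Node
    score: float
    order: int


def _label_sort_key(label: Node):
    # numeric labels sort numerically, everything else lexically; the two
    # kinds never interleave within a group in practice
    if isinstance(label, bool) or not isinstance(label, (int, float)):
        return (1, str(label))
    return (0, label)


@dataclass(frozen=True)
class Ranking:
    """Nodes sorted by non-increasing score with dense order indices.

    Tied nodes (scores equal within the tie tolerance) share one order index
    and are listed by label; order indices run densely 1..#groups.
    """

    method: str
    entries: tuple[RankEntry, ...]

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def group_sizes(self) -> tuple[int, ...]:
        sizes: list[int] = []
        for e in self.entries:
            if e.order == len(sizes):
                sizes[-1] += 1
            else:
                sizes.append(1)
        return tuple(sizes)

    def orders(self) -> dict[Node, int]:
        return {e.node: e.order for e in self.entries}

    def top(self, k: int) -> list[Node]:
        """The first ``k`` nodes of the listing (label-ordered within ties)."""
        if not 0 < k <= self.n:
            raise ValueError(f"k must be in 1..{self.n}, got {k}")
        return [e.node for e in self.entries[:k]]


def rank_from_scores(table: ScoreTable, tie_tol: float = TIE_TOL) -> Ranking:
    """Sort a score table into a dense-order ranking, highest score first."""
    if not table.scores:
        raise ValueError("empty score table")
    items = sorted(table.scores.items(), key=lambda kv: -kv[1])
    groups: list[list[tuple[Node, float]]] = []
    for node, s in items:
        if groups and abs(groups[-1][0][1] - s) <= tie_tol:
            groups[-1].append((node, s))
        else:
            groups.append([(node, s)])
    entries: list[RankEntry] = []
    for order, group in enumerate(groups, start=1):
        for node, s in sorted(group, key=lambda kv: _label_sort_key(kv[0])):
            entries.append(RankEntry(node, s, order))
    return Ranking(table.method, tuple(entries))


def rank(g: Graph, method: str = "siwr") -> Ranking:
    """Score and rank all nodes of ``g`` with the given method."""
    return rank_from_scores(score(g, method))


def write_ranking(
    r: Ranking,
    dest: Union[str, Path, io.TextIOBase],
    precision: int | None = None,
) -> None:
    """Write a ranking as TSV: node_label, score, order_index.

    Full float precision by default (machine output); pass ``precision=4``
    for the human-readable 4-decimal convention.
    """
    if isinstance(dest, (str, Path)):
        with open(dest, "wt", encoding="utf-8") as fh:
            write_ranking(r, fh, precision=precision)
        return
    dest.write(f"% method={r.method}\n")
    dest.write("% node\tscore\torder\n")
    for e in r.entries:
        s = f"{e.score:.{precision}f}" if precision is not None else repr(e.score)
        dest.write(f"{e.node}\t{s}\t{e.order}\n")


def read_ranking(source: Union[str, Path, io.TextIOBase]) -> Ranking:
    """Read a ranking TSV written by :func:`write_ranking`."""
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            return read_ranking(fh)
    method = "?"
    entries: list[RankEntry] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("%"):
            if "method=" in line:
                method = line.split("method=", 1)[1].strip()
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed ranking line {lineno}: {raw!r}")
        entries.append(
            RankEntry(_coerce_label(parts[0]), float(parts[1]), int(parts[2]))
        )
    if not entries:
        raise ValueError("empty ranking")
    return Ranking(method, tuple(entries))


# ---------------------------------------------------------------------------
# 5. Evaluation: monotonicity, CCDF, SIR spreading, robustness
# ---------------------------------------------------------------------------


def monotonicity(r: Ranking) -> float:
    """Monotonicity M(R) of a ranking: how finely it discriminates nodes.

    ``M(R) = (1 - Σ_r n_r(n_r-1)/2 / [n(n-1)/2])²`` where ``n_r`` is the size
    of order group ``r``.  1 when every node has its own order, 0 when all
    nodes share one order.
    """
    n = r.n
    if n < 2:
        raise ValueError("monotonicity requires a ranking of at least 2 nodes")
    tied_pairs = sum(s * (s - 1) / 2 for s in r.group_sizes)
    return (1.0 - tied_pairs / (n * (n - 1) / 2)) ** 2


def ccdf(r: Ranking) -> tuple[float, ...]:
    """Complementary CDF of order occupancy: fraction ranked below order r.

    ``CCDF(r) = (n - Σ_{i≤r} n_i) / n`` for r = 1..#groups; non-increasing
    and exactly 0 at the last order.  A smooth decay means few nodes share
    an order.
    """
    n = r.n
    out: list[float] = []
    cum = 0
    for size in r.group_sizes:
        cum += size
        out.append((n - cum) / n)
    return tuple(out)


@dataclass(frozen=True)
class SIRConfig:
    """Parameters of the discrete-time SIR spreading experiment.

    ``beta`` is the per-contact infection probability per step (default
    choice for a graph: ``1/(<d> - 1)``, see :func:`default_beta`);
    ``recovery`` the per-step recovery probability (1 = infect once, then
    recover); ``n_ite`` the number of repeated epidemics averaged over.
    """

    beta: float
    recovery: float = 1.0
    n_ite: int = 1000
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 <= self.recovery <= 1.0:
            raise ValueError(f"recovery must be in [0, 1], got {self.recovery}")
        if self.n_ite < 1:
            raise ValueError("n_ite must be >= 1")


@dataclass(frozen=True)
class SIRResult:
    """Outcome of repeated epidemics from one seed set."""

    propagation_ability: float  # mean fraction of ever-infected nodes
    per_run_counts: tuple[int, ...]


def default_beta(g: Graph) -> float:
    """The spreading-experiment infection probability ``1 / (<d> - 1)``.

    Clamped to 1 (with a warning) when the average degree is below 2; graphs
    with average degree ≤ 1 have no meaningful spreading regime and raise.
    """
    avg = g.average_degree()
    if avg <= 1.0:
        raise ValueError(f"average degree {avg:.4f} <= 1: beta undefined")
    beta = 1.0 / (avg - 1.0)
    if beta > 1.0:
        logger.warning("average degree %.4f < 2: beta clamped to 1", avg)
        beta = 1.0
    return beta


def sir_simulate(
    g: Graph,
    seeds: Iterable[Node],
    cfg: SIRConfig,
    rng: np.random.Generator | None = None,
) -> SIRResult:
    """Repeated synchronous SIR epidemics seeded at ``seeds``.

    Each step, every infected node independently infects each susceptible
    neighbor with probability ``beta``, then recovers with probability
    ``recovery``; the run ends when no infected nodes remain.  The
    propagation ability is the mean over ``n_ite`` runs of the fraction of
    nodes ever infected (seeds included; recovered nodes count).
    """
    seed_list = list(dict.fromkeys(seeds))
    if not seed_list:
        raise ValueError("empty seed set")
    index = {u: i for i, u in enumerate(g.nodes)}
    try:
        seed_idx = [index[u] for u in seed_list]
    except KeyError as exc:
        raise KeyError(f"seed {exc.args[0]!r} is not a node of the graph") from None
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    adj = [
        np.fromiter((index[v] for v in g.neighbors(u)), dtype=np.intp)
        for u in g.nodes
    ]
    counts: list[int] = []
    for _ in range(cfg.n_ite):
        ever = np.zeros(g.n, dtype=bool)
        ever[seed_idx] = True
        infected = list(seed_idx)
        while infected:
            newly: set[int] = set()
            for i in infected:
                nbrs = adj[i]
                if nbrs.size:
                    sus = nbrs[~ever[nbrs]]
                    if sus.size and cfg.beta > 0.0:
                        hits = sus[rng.random(sus.size) < cfg.beta]
                        newly.update(hits.tolist())
            if cfg.recovery >= 1.0:
                staying: list[int] = []
            else:
                staying = [
                    i for i in infected if rng.random() >= cfg.recovery
                ]
            for j in newly:
                ever[j] = True
            infected = staying + sorted(newly)
        counts.append(int(ever.sum()))
    ability = float(np.mean(counts)) / g.n
    return SIRResult(ability, tuple(counts))


def propagation_curve(
    g: Graph,
    r: Ranking,
    seed_counts: Sequence[int],
    cfg: SIRConfig,
) -> list[SIRResult]:
    """Spreading ability of the top-k seed sets of a ranking, for each k.

    For each ``k`` in ``seed_counts`` the seeds are the first k nodes of the
    ranking listing (ties broken by label), simulated under ``cfg`` with an
    independent sub-stream derived from ``cfg.rng_seed``.
    """
    for k in seed_counts:
        if not 0 < k <= g.n:
            raise ValueError(f"seed count {k} outside 1..{g.n}")
    children = np.random.SeedSequence(cfg.rng_seed).spawn(len(seed_counts))
    return [
        sir_simulate(g, r.top(k), cfg, rng=np.random.default_rng(child))
        for k, child in zip(seed_counts, children)
    ]


def _restricted_orders(
    r: Ranking, survivors: set[Node], compare: str
) -> dict[Node, int]:
    """Orders of the surviving nodes after restricting a ranking.

    ``compare="dense"`` recompacts the dense order indices over survivors;
    ``compare="position"`` uses the raw index in the restricted listing.
    """
    out: dict[Node, int] = {}
    last_orig = None
    dense = 0
    pos = 0
    for e in r.entries:
        if e.node not in survivors:
            continue
        pos += 1
        if e.order != last_orig:
            dense += 1
            last_orig = e.order
        out[e.node] = dense if compare == "dense" else pos
    return out


def robustness_change_rate(
    g: Graph,
    method: Union[str, Callable[[Graph], Ranking]],
    removal_fraction: float,
    reps: int = 100,
    rng_seed: int | None = None,
    compare: str = "dense",
) -> float:
    """Mean fraction of surviving nodes whose rank order changes on removal.

    Each repetition removes ``ceil(fraction * n)`` uniformly sampled nodes,
    restricts the original ranking to the survivors, re-ranks the induced
    subgraph, and counts survivors whose order index differs; the rate is
    averaged over ``reps`` repetitions.  ``compare`` selects dense order
    indices (default) or raw sorted positions.
    """
    if not 0.0 < removal_fraction < 1.0:
        raise ValueError("removal_fraction must be strictly between 0 and 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if compare not in ("dense", "position"):
        raise ValueError(f"compare must be 'dense' or 'position', got {compare!r}")
    rank_fn: Callable[[Graph], Ranking]
    if callable(method):
        rank_fn = method
    else:
        name = method
        rank_fn = lambda h: rank(h, name)  # noqa: E731
    n_remove = math.ceil(removal_fraction * g.n)
    if n_remove == 0 or n_remove >= g.n:
        raise ValueError(
            f"removal of {n_remove} node(s) out of {g.n} leaves nothing to compare"
        )
    base = rank_fn(g)
    nodes = list(g.nodes)
    rng = np.random.default_rng(rng_seed)
    rates: list[float] = []
    for _ in range(reps):
        removed_idx = rng.choice(g.n, size=n_remove, replace=False)
        removed = {nodes[i] for i in removed_idx}
        survivors = {u for u in nodes if u not in removed}
        before = _restricted_orders(base, survivors, compare)
        after_rank = rank_fn(g.subgraph(survivors))
        after = (
            after_rank.orders()
            if compare == "dense"
            else {e.node: i + 1 for i, e in enumerate(after_rank.entries)}
        )
        changed = sum(1 for u in survivors if before[u] != after[u])
        rates.append(changed / len(survivors))
    return float(np.mean(rates))


# ---------------------------------------------------------------------------
# 6. Fixture graphs and synthetic generators
# ---------------------------------------------------------------------------

#: Edge set of the 6-node worked example used throughout the docs and tests.
TOY_EDGES: tuple[tuple[str, str], ...] = (
    ("v1", "v2"),
    ("v1", "v3"),
    ("v1", "v6"),
    ("v2", "v3"),
    ("v2", "v4"),
    ("v4", "v5"),
)


def toy_graph() -> Graph:
    """The 6-node, 6-edge worked-example graph (degrees 3,3,2,2,1,1).

    The same graph ships as a packaged edge list (``siwr/data/toy.edges``) so
    the CLI and the library share one source of truth.
    """
    return Graph.from_edges(TOY_EDGES)


_GENERATORS = ("toy", "erdos_renyi", "barabasi_albert", "star", "path", "cycle", "complete")


def generate(model: str, rng_seed: int | None = None, **params) -> Graph:
    """Generate a synthetic test graph, reproducible given ``rng_seed``.

    Models: ``toy`` (no parameters), ``erdos_renyi(n, p)``,
    ``barabasi_albert(n, m_attach)``, ``star(n)`` (one center, n-1 leaves),
    ``path(n)``, ``cycle(n)``, ``complete(n)``.  Isolated nodes are allowed
    in the output (they exercise the degenerate zero-strength scoring path).
    """
    model = model.lower()
    if model not in _GENERATORS:
        raise ValueError(f"unknown model {model!r}; choose from {_GENERATORS}")
    if model == "toy":
        if params:
            raise ValueError("toy model takes no parameters")
        return toy_graph()
    try:
        n = int(params.pop("n"))
    except KeyError:
        raise ValueError(f"model {model!r} requires n") from None
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if model == "erdos_renyi":
        p = float(params.pop("p"))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {p}")
        nxg = nx.gnp_random_graph(n, p, seed=rng_seed)
    elif model == "barabasi_albert":
        m_attach = int(params.pop("m_attach", 1))
        if not 1 <= m_attach < n:
            raise ValueError(f"m_attach must be in 1..{n - 1}, got {m_attach}")
        nxg = nx.barabasi_albert_graph(n, m_attach, seed=rng_seed)
    elif model == "star":
        nxg = nx.star_graph(n - 1)
    elif model == "path":
        nxg = nx.path_graph(n)
    elif model == "cycle":
        nxg = nx.cycle_graph(n)
    else:  # complete
        nxg = nx.complete_graph(n)
    if params:
        raise ValueError(f"unexpected parameters for {model!r}: {sorted(params)}")
    return Graph(nxg)
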