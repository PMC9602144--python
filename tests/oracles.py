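"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from the defining formulas against the
dense adjacency matrix, deliberately sharing no code path with the package:
matrix-based entropy scoring, Floyd–Warshall distances, a dense
eigendecomposition, and naive peeling loops.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall

from siwr import Graph


def adjacency(g: Graph) -> np.ndarray:
    nodes = g.nodes
    a = np.zeros((g.n, g.n))
    for u, v in g.edges():
        i, j = nodes.index(u), nodes.index(v)
        a[i, j] = a[j, i] = 1.0
    return a


def siwr_scores_naive(g: Graph) -> dict:
    """Direct matrix evaluation of the weighting + entropy formulas."""
    a = adjacency(g)
    d = a.sum(axis=1)
    n = g.n
    w_edge = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                w_edge[i, j] = math.log2(d[i] * d[j])
    strength = w_edge.sum(axis=1)
    scores = {}
    for i, u in enumerate(g.nodes):
        gamma = [j for j in range(n) if a[i, j]] + [i]
        total = sum(strength[j] for j in gamma)
        if total <= 0:
            scores[u] = 0.0
            continue
        h = 0.0
        for j in gamma:
            p = strength[j] / total
            if p > 0:
                h -= p * math.log2(p)
        scores[u] = h
    return scores


def distances_naive(g: Graph) -> np.ndarray:
    """All-pairs hop counts via Floyd–Warshall; unreachable encoded as 0."""
    d = floyd_warshall(adjacency(g), directed=False, unweighted=True)
    d[np.isinf(d)] = 0.0
    return d


def closeness_naive(g: Graph) -> dict:
    d = distances_naive(g)
    out = {}
    for i, u in enumerate(g.nodes):
        s = d[i].sum()
        out[u] = (g.n - 1) / s if s > 0 else 0.0
    return out


def eigenvector_naive(g: Graph) -> dict:
    """Principal eigenvector from a full symmetric eigendecomposition."""
    a = adjacency(g)
    vals, vecs = np.linalg.eigh(a)
    v = vecs[:, int(np.argmax(vals))]
    v = np.abs(v)
    v /= np.linalg.norm(v)
    return dict(zip(g.nodes, v.tolist()))


def ec_principal_residual(g: Graph, scores: dict) -> float:
    """Distance of a score vector from the principal eigenspace of A.

    When the largest adjacency eigenvalue is degenerate (e.g. two identical
    components) any unit vector in the eigenspace is a valid centrality, so
    equivalence is checked against the eigh-computed eigenspace rather than
    one arbitrary basis vector.
    """
    a = adjacency(g)
    vals, vecs = np.linalg.eigh(a)
    lam = vals.max()
    basis = vecs[:, np.abs(vals - lam) < 1e-9]
    v = np.array([scores[u] for u in g.nodes])
    return float(np.max(np.abs(v - basis @ (basis.T @ v))))


def k_shell_naive(g: Graph) -> dict:
    """Peeling at degree thresholds 1, 2, …, cascading within each stage."""
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(g.edges())
    labels = {}
    k = 1
    while h.number_of_nodes() > 0:
        stripped = True
        while stripped:
            batch = [u for u, d in h.degree() if d <= k]
            stripped = bool(batch)
            for u in batch:
                labels[u] = k
            h.remove_nodes_from(batch)
        k += 1
    return {u: float(labels[u]) for u in g.nodes}


def improved_k_shell_naive(g: Graph) -> dict:
    """Round-by-round minimum-degree removal, label = round number."""
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(g.edges())
    labels = {}
    t = 0
    while h.number_of_nodes() > 0:
        t += 1
        dmin = min(d for _, d in h.degree())
        batch = [u for u, d in h.degree() if d == dmin]
        for u in batch:
            labels[u] = t
        h.remove_nodes_from(batch)
    return {u: float(labels[u]) for u in g.nodes}


def random_graph_corpus(count: int, n_max: int, seed0: int = 0) -> list[Graph]:
    """Small Erdős–Rényi graphs of varied size/density, some disconnected,
    each with at least one edge."""
    out = []
    s = seed0
    while len(out) < count:
        rng = np.random.default_rng(s)
        n = int(rng.integers(3, n_max + 1))
        p = float(rng.uniform(0.1, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        s += 1
        if g.number_of_edges() == 0:
            continue
        out.append(Graph(g))
    return out
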