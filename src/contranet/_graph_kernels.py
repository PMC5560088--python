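"""Numba kernels for weighted-graph metrics and degree-preserving rewiring.

Dense 45-node connectivity graphs are small enough that Floyd-Warshall on
a contiguous matrix beats sparse Dijkstra, and the null-model loop (1000
rewired networks per graph) makes a compiled inner loop worthwhile.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.inf


@njit(cache=True)
def floyd_warshall(d: np.ndarray) -> None:
    """In-place min-plus all-pairs shortest paths on a length matrix."""
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            dik = d[i, k]
            if dik == INF:
                continue
            for j in range(n):
                alt = dik + d[k, j]
                if alt < d[i, j]:
                    d[i, j] = alt


@njit(cache=True)
def shortest_path_lengths(w: np.ndarray) -> np.ndarray:
    """Length matrix with edge length 1/weight, then all-pairs shortest paths."""
    n = w.shape[0]
    d = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                d[i, j] = 0.0
            elif w[i, j] > 0.0:
                d[i, j] = 1.0 / w[i, j]
            else:
                d[i, j] = INF
    floyd_warshall(d)
    return d


@njit(cache=True)
def global_efficiency_kernel(w: np.ndarray) -> float:
    """Mean of 1/d over ordered node pairs; disconnected pairs contribute 0."""
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path_lengths(w)
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i, j] < INF:
                acc += 1.0 / d[i, j]
    return acc / (n * (n - 1))


@njit(cache=True)
def local_efficiency_kernel(w: np.ndarray) -> float:
    """Weighted local efficiency averaged over all nodes.

    Per node u with neighbours N(u): shortest paths are computed on the
    subgraph induced on N(u) with edge lengths w^(-1/3) (cube-root
    symmetrization), and each neighbour pair (j, h) contributes
    (w_uj * w_uh)^(1/3) / d_jh, normalized by k(k-1).  Nodes with fewer
    than two neighbours contribute 0.
    """
    n = w.shape[0]
    wc = np.cbrt(w)
    total = 0.0
    nbrs = np.empty(n, dtype=np.int64)
    for u in range(n):
        k = 0
        for v in range(n):
            if w[u, v] > 0.0:
                nbrs[k] = v
                k += 1
        if k < 2:
            continue
        d = np.empty((k, k))
        for a in range(k):
            for b in range(k):
                if a == b:
                    d[a, b] = 0.0
                else:
                    wab = w[nbrs[a], nbrs[b]]
                    d[a, b] = 1.0 / np.cbrt(wab) if wab > 0.0 else INF
        floyd_warshall(d)
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and d[a, b] < INF:
                    acc += wc[u, nbrs[a]] * wc[u, nbrs[b]] / d[a, b]
        total += acc / (k * (k - 1))
    return total / n


@njit(cache=True)
def double_edge_swap_kernel(
    edges: np.ndarray, n_nodes: int, n_attempts: int, seed: int
) -> int:
    """Degree-preserving double-edge swaps on an undirected edge list, in place.

    Picks two edges (a,b), (c,d), randomly orients one, and rewires to
    (a,d), (c,b) when this creates neither a self-loop nor a multi-edge.
    Returns the number of successful swaps.
    """
    np.random.seed(seed)
    m = edges.shape[0]
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    for e in range(m):
        adj[edges[e, 0], edges[e, 1]] = True
        adj[edges[e, 1], edges[e, 0]] = True
    swaps = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.random() < 0.5:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        edges[e1, 0], edges[e1, 1] = a, d
        edges[e2, 0], edges[e2, 1] = c, b
        swaps += 1
    return swaps
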