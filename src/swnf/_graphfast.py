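"""Compiled kernels for binary-graph metrics.

These are the hot path of the online feedback loop: every score update
needs clustering, path length and a degree-preserving null ensemble for a
35-node graph, thousands of times per simulated session.  The public API
lives in :mod:`swnf.swmetrics`; nothing here validates its inputs.

All kernels take a boolean adjacency matrix (symmetric, zero diagonal).
"""

import numpy as np
from numba import njit

__all__ = [
    "clustering_mean",
    "clustering_nodes",
    "path_length_finite",
    "double_edge_swap",
    "sigma_with_nulls",
]


@njit(cache=True)
def clustering_nodes(adj):
    """Watts-Strogatz local clustering per node; degree<2 contributes 0."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        deg = 0
        for j in range(n):
            if adj[i, j]:
                deg += 1
        if deg < 2:
            continue
        tri = 0
        for j in range(n):
            if not adj[i, j]:
                continue
            for k in range(j + 1, n):
                if adj[i, k] and adj[j, k]:
                    tri += 1
        out[i] = 2.0 * tri / (deg * (deg - 1))
    return out


@njit(cache=True)
def clustering_mean(adj):
    return clustering_nodes(adj).mean()


@njit(cache=True)
def path_length_finite(adj):
    """Mean shortest-path length over ordered pairs at finite distance.

    Disconnected pairs are excluded from numerator and denominator; a graph
    with no finite pair returns NaN (caller decides how to fail).
    """
    n = adj.shape[0]
    total = 0.0
    count = 0
    dist = np.empty(n, dtype=np.int64)
    queue = np.empty(n, dtype=np.int64)
    for s in range(n):
        for v in range(n):
            dist[v] = -1
        dist[s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            for v in range(n):
                if adj[u, v] and dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue[tail] = v
                    tail += 1
        for v in range(n):
            if v != s and dist[v] > 0:
                total += dist[v]
                count += 1
    if count == 0:
        return np.nan
    return total / count


@njit(cache=True)
def double_edge_swap(adj, edges, target_swaps, max_tries, seed):
    """Maslov-Sneppen rewiring in place; returns achieved swap count.

    Picks two edges (a,b),(c,d), flips orientation of the second with
    probability 1/2, and replaces them with (a,d),(c,b) when that creates
    neither self-loops nor duplicate edges.  Degree sequence is invariant.
    """
    np.random.seed(seed)
    m = edges.shape[0]
    done = 0
    tries = 0
    while done < target_swaps and tries < max_tries:
        tries += 1
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[e1, 0], edges[e1, 1] = a, d
        edges[e2, 0], edges[e2, 1] = c, b
        done += 1
    return done


@njit(cache=True)
def _edge_list(adj):
    n = adj.shape[0]
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                m += 1
    edges = np.empty((m, 2), dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                edges[k, 0] = i
                edges[k, 1] = j
                k += 1
    return edges


@njit(cache=True)
def sigma_with_nulls(adj, n_nulls, swaps_per_edge, seed):
    """(C, L, gamma, lam, sigma) against a Maslov-Sneppen null ensemble.

    Null seeds are seed..seed+n_nulls-1, so a fixed seed reproduces the
    ensemble exactly.
    """
    C = clustering_mean(adj)
    L = path_length_finite(adj)
    edges = _edge_list(adj)
    m = edges.shape[0]
    c_sum = 0.0
    l_sum = 0.0
    for q in range(n_nulls):
        null_adj = adj.copy()
        null_edges = edges.copy()
        double_edge_swap(null_adj, null_edges, swaps_per_edge * m,
                         100 * m, seed + q)
        c_sum += clustering_mean(null_adj)
        l_sum += path_length_finite(null_adj)
    c_null = c_sum / n_nulls
    l_null = l_sum / n_nulls
    gamma = C / c_null
    lam = L / l_null
    return C, L, gamma, lam, gamma / lam
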