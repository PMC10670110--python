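"""Small-world topology metrics with degree-preserving null normalization.

The small-worldness index follows Humphries: sigma = gamma / lambda, where
gamma is the clustering coefficient and lambda the characteristic path
length, each normalized by the mean over an ensemble of degree-matched
random graphs (Maslov-Sneppen double-edge swaps, 30 nulls by default).

Conventions, chosen once and applied identically to source graphs and
nulls so the normalization stays comparable:

* clustering: Watts-Strogatz node average; degree<2 nodes contribute 0;
* path length: mean over ordered pairs at finite distance (disconnected
  pairs are dropped from numerator and denominator);
* nulls: >= 10 successful swaps per edge, connectivity not enforced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _graphfast

__all__ = [
    "GraphMetrics",
    "DEFAULT_NULLS",
    "SWAPS_PER_EDGE",
    "clustering_coefficient",
    "char_path_length",
    "random_nulls",
    "small_worldness",
    "sigma_of_graph",
    "degree_distribution",
    "PAPER_DEGREE_BINS",
]

DEFAULT_NULLS = 30
SWAPS_PER_EDGE = 10

#: degree bins reported for the group contrast (inclusive ranges)
PAPER_DEGREE_BINS = ((0, 1), (6, 15), (16, 20))


@dataclass(frozen=True)
class GraphMetrics:
    C: float
    L: float
    gamma: float
    lam: float
    sigma: float
    sparsity: float | None = None
    null_count: int = DEFAULT_NULLS


def _as_adj(graph) -> np.ndarray:
    adj = np.ascontiguousarray(np.asarray(graph, dtype=bool))
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if adj.diagonal().any():
        raise ValueError("self-loops are not allowed")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    return adj


def clustering_coefficient(graph) -> float:
    """Node-averaged Watts-Strogatz clustering coefficient."""
    return float(_graphfast.clustering_mean(_as_adj(graph)))


def char_path_length(graph) -> float:
    """Characteristic path length under the finite-pairs rule."""
    adj = _as_adj(graph)
    if adj.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    L = float(_graphfast.path_length_finite(adj))
    if np.isnan(L):
        raise ValueError("graph has no finite node pair (no edges)")
    return L


def random_nulls(graph, count: int = DEFAULT_NULLS, seed: int = 0,
                 swaps_per_edge: int = SWAPS_PER_EDGE) -> np.ndarray:
    """Degree-preserving null ensemble as a (count, n, n) boolean array."""
    adj = _as_adj(graph)
    edges = np.array(np.nonzero(np.triu(adj))).T
    m = edges.shape[0]
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    out = np.empty((count, adj.shape[0], adj.shape[0]), dtype=bool)
    for q in range(count):
        null_adj = adj.copy()
        achieved = _graphfast.double_edge_swap(
            null_adj, edges.copy(), swaps_per_edge * m, 100 * m,
            int(seed) + q)
        if achieved < swaps_per_edge * m:
            warnings.warn(
                f"null {q}: swap saturation, achieved {achieved} of "
                f"{swaps_per_edge * m} swaps")
        out[q] = null_adj
    return out


def small_worldness(graph, nulls: np.ndarray,
                    sparsity: float | None = None) -> GraphMetrics:
    """gamma, lambda, sigma of ``graph`` against a given null ensemble."""
    adj = _as_adj(graph)
    C = clustering_coefficient(adj)
    L = char_path_length(adj)
    c_null = float(np.mean([_graphfast.clustering_mean(
        np.ascontiguousarray(n)) for n in np.asarray(nulls, dtype=bool)]))
    l_null = float(np.mean([_graphfast.path_length_finite(
        np.ascontiguousarray(n)) for n in np.asarray(nulls, dtype=bool)]))
    if c_null == 0 or l_null == 0 or np.isnan(l_null):
        raise ValueError("degenerate null ensemble (zero mean C or L)")
    gamma = C / c_null
    lam = L / l_null
    return GraphMetrics(C=C, L=L, gamma=gamma, lam=lam, sigma=gamma / lam,
                        sparsity=sparsity, null_count=len(nulls))


def sigma_of_graph(graph, n_nulls: int = DEFAULT_NULLS, seed: int = 0,
                   sparsity: float | None = None) -> GraphMetrics:
    """One-call sigma: generates the null ensemble internally (fast path)."""
    adj = _as_adj(graph)
    if int(np.triu(adj).sum()) < 2:
        raise ValueError("need at least 2 edges to rewire")
    C, L, gamma, lam, sigma = _graphfast.sigma_with_nulls(
        adj, n_nulls, SWAPS_PER_EDGE, int(seed))
    if np.isnan(L):
        raise ValueError("graph has no finite node pair (no edges)")
    return GraphMetrics(C=float(C), L=float(L), gamma=float(gamma),
                        lam=float(lam), sigma=float(sigma),
                        sparsity=sparsity, null_count=n_nulls)


def degree_distribution(graphs, bins=None) -> np.ndarray:
    """Average per-graph degree histograms, normalized to probability mass.

    ``graphs`` is an iterable of adjacency matrices sharing the node count.
    With ``bins`` (inclusive (lo, hi) ranges) the averaged mass is summed
    per bin instead of returned per degree value.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("no graphs given")
    n = np.asarray(graphs[0]).shape[0]
    mass = np.zeros(n)
    for g in graphs:
        adj = _as_adj(g)
        if adj.shape[0] != n:
            raise ValueError("graphs must share the node count")
        deg = adj.sum(axis=1).astype(int)
        mass += np.bincount(deg, minlength=n)[:n] / n
    mass /= len(graphs)
    if bins is None:
        return mass
    return np.array([mass[lo:hi + 1].sum() for lo, hi in bins])
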