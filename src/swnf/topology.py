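"""Higher-order network analyses: edge reallocation and the rewiring continuum.

Three questions about how upregulation reshapes the network:

* which edges strengthen or weaken (UP minus DOWN, edge-wise t tests), and
  whether the weakening edges attach to higher-degree nodes than the
  strengthening ones (reallocation from rich to poor nodes);
* whether a node's degree predicts its degree change (negative correlation
  = hub pruning);
* where the observed (C, L) pair sits in the family of randomly rewired
  Watts-Strogatz graphs: an effective rewiring probability with a
  simulation-based uncertainty interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats as swstats
from .netbuild import threshold_binarize
from .swmetrics import clustering_coefficient, char_path_length
from .synthgen import make_ws_graph

__all__ = [
    "EdgeChangeMap",
    "WSPlacement",
    "BRODMANN_BY_CHANNEL",
    "edge_reallocation",
    "degree_delta_correlation",
    "infer_rewiring_p",
]

#: channel (1-based) -> (Brodmann-area label, hemisphere); static probe
#: registration lookup for the 35-channel frontal montage.
_REGIONS = {
    "dorsolateral prefrontal": ([1, 10, 18, 19, 29], [16, 24, 25, 28, 30]),
    "premotor / supplementary motor": ([2, 3, 4, 12], [5, 6, 13]),
    "frontal eye fields": ([11, 20, 21, 26], [7, 14, 15, 22, 23, 27]),
    "pars triangularis Broca": ([9], [8, 17]),
    "frontopolar": ([31, 34], [32, 33, 35]),
}
BRODMANN_BY_CHANNEL = {}
for _name, (_right, _left) in _REGIONS.items():
    for _ch in _right:
        BRODMANN_BY_CHANNEL[_ch] = (_name, "right")
    for _ch in _left:
        BRODMANN_BY_CHANNEL[_ch] = (_name, "left")


@dataclass
class EdgeChangeMap:
    n_nodes: int
    edge_index: np.ndarray       # (n_edges, 2) upper-triangle pairs
    mean_diff: np.ndarray        # per-edge UP - DOWN mean Fisher z
    selected: np.ndarray         # significance mask
    increased: np.ndarray        # indices into edge_index
    decreased: np.ndarray
    mean_degree_increased: float | None
    mean_degree_decreased: float | None
    pooled_degree: np.ndarray    # node degrees of the pooled mean graph


def _edge_pairs(n: int) -> np.ndarray:
    iu = np.triu_indices(n, 1)
    return np.column_stack(iu)


def edge_reallocation(group_a: np.ndarray, group_b: np.ndarray,
                      n_nodes: int, alpha: float = 0.01,
                      sparsity: float = 0.3) -> EdgeChangeMap:
    """Edge-wise contrast (A - B) with endpoint-degree summaries.

    ``group_a`` / ``group_b``: (subjects x edges) per-subject mean Fisher-z
    summaries over the upper-triangle pair order.  Endpoint degrees are
    measured on the pooled mean graph (both groups averaged, thresholded at
    the working sparsity).
    """
    pairs = _edge_pairs(n_nodes)
    if group_a.shape[1] != len(pairs):
        raise ValueError("edge count does not match n_nodes")
    res = swstats.edgewise_ttest(group_a, group_b, alpha=alpha)
    diff = res["mean_diff"].to_numpy()
    selected = res["selected"].to_numpy()
    increased = np.flatnonzero(selected & (diff > 0))
    decreased = np.flatnonzero(selected & (diff < 0))

    pooled = np.vstack([group_a, group_b]).mean(axis=0)
    z = np.zeros((n_nodes, n_nodes))
    z[pairs[:, 0], pairs[:, 1]] = pooled
    adj = threshold_binarize(z + z.T, sparsity)
    degree = adj.sum(axis=1).astype(float)

    def _mean_endpoint_degree(idx):
        if idx.size == 0:
            return None
        return float(degree[pairs[idx]].mean())

    return EdgeChangeMap(
        n_nodes=n_nodes, edge_index=pairs, mean_diff=diff,
        selected=selected, increased=increased, decreased=decreased,
        mean_degree_increased=_mean_endpoint_degree(increased),
        mean_degree_decreased=_mean_endpoint_degree(decreased),
        pooled_degree=degree)


def degree_delta_correlation(change: EdgeChangeMap) -> swstats.TestOutcome:
    """Pearson r between node degree and its signed degree change.

    Delta-k per node counts +1 for each selected increased edge at the
    node and -1 for each selected decreased edge (the drawing rule of the
    reallocation analysis: only significant edges enter).
    """
    dk = np.zeros(change.n_nodes)
    for idx, sign in ((change.increased, 1.0), (change.decreased, -1.0)):
        for i, j in change.edge_index[idx]:
            dk[i] += sign
            dk[j] += sign
    if np.allclose(dk, dk[0]):
        raise ValueError("uniform degree change; correlation undefined")
    return swstats.pearson_corr(change.pooled_degree, dk)


@dataclass
class WSPlacement:
    p_hat: float
    p_interval: tuple
    grid: np.ndarray
    c_curve: np.ndarray
    l_curve: np.ndarray
    c_sd: np.ndarray
    l_sd: np.ndarray
    boundary: bool


def _family_curves(grid, n, k, seeds_per_point, rng):
    c = np.empty((len(grid), seeds_per_point))
    l = np.empty((len(grid), seeds_per_point))
    for gi, p in enumerate(grid):
        for s in range(seeds_per_point):
            net = make_ws_graph(n, k, p, seed=int(rng.integers(2 ** 31 - 1)))
            c[gi, s] = clustering_coefficient(net.adjacency)
            l[gi, s] = char_path_length(net.adjacency)
    return c.mean(axis=1), l.mean(axis=1), c.std(axis=1), l.std(axis=1)


def infer_rewiring_p(C: float, L: float, n: int = 35, k: int = 10,
                     seeds_per_point: int = 100, seed: int = 0,
                     n_grid: int = 13) -> WSPlacement:
    """Place observed (C, L) on the Watts-Strogatz rewiring continuum.

    Simulates C(p) and L(p) on a log-spaced grid (plus the p=0 lattice),
    scores each grid point by the squared distance in units of the family
    SD per metric, and refines once around the best point.  An observation
    outside the family envelope snaps to the boundary and is flagged.
    """
    rng = np.random.default_rng(seed)
    grid = np.concatenate([[0.0], np.logspace(-3, 0, n_grid - 1)])

    def _score(grid_):
        cm, lm, cs, ls = _family_curves(grid_, n, k, seeds_per_point, rng)
        cs = np.where(cs > 0, cs, np.median(cs[cs > 0]) if (cs > 0).any()
                      else 1.0)
        ls = np.where(ls > 0, ls, np.median(ls[ls > 0]) if (ls > 0).any()
                      else 1.0)
        d = ((C - cm) / cs) ** 2 + ((L - lm) / ls) ** 2
        return d, cm, lm, cs, ls

    d, cm, lm, cs, ls = _score(grid)
    best = int(np.argmin(d))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    fine = np.linspace(lo, hi, 7)
    d2, *_ = _score(fine)
    best2 = int(np.argmin(d2))
    p_hat = float(fine[best2])
    if 0 < best2 < len(fine) - 1:
        # parabolic vertex through the three points around the minimum
        y0, y1, y2 = d2[best2 - 1], d2[best2], d2[best2 + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            shift = 0.5 * (y0 - y2) / denom
            p_hat = float(np.clip(fine[best2]
                                  + shift * (fine[1] - fine[0]),
                                  fine[0], fine[-1]))
    # uncertainty: fine-grid points within one distance unit of the optimum
    near = fine[d2 <= d2[best2] + 1.0]
    interval = (float(near.min()), float(near.max()))
    boundary = bool(
        best in (0, len(grid) - 1)
        and (np.min(d) > 2.0 or p_hat in (grid[0], grid[-1])))
    return WSPlacement(p_hat=p_hat, p_interval=interval, grid=grid,
                       c_curve=cm, l_curve=lm, c_sd=cs, l_sd=ls,
                       boundary=boundary)
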