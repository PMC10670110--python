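"""Windowed functional-connectivity graphs from hemodynamic time series.

The online feedback system correlates the trailing 5 s (128 samples at
25.6 Hz) of all channel pairs, Fisher-transforms the correlations, and keeps
the strongest 30% of |Z| values as edges of a binary, undirected graph.  The
offline analyses do the same with non-overlapping 25 s windows.  This module
implements that chain for an arbitrary window specification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WindowSpec",
    "ONLINE_WINDOW",
    "OFFLINE_WINDOW",
    "window_series",
    "correlation_matrix",
    "fisher_z",
    "threshold_binarize",
    "edge_count_for_sparsity",
    "connectivity_graphs",
]

#: clamp |r| below 1 before the Fisher transform
_R_CLAMP = 1.0 - 1e-7


@dataclass(frozen=True)
class WindowSpec:
    """Trailing analysis windows: ``length`` samples advancing by ``step``."""

    length: int
    step: int

    def __post_init__(self):
        if self.length <= 0 or self.step <= 0:
            raise ValueError("window length and step must be positive")
        if self.step > self.length:
            # non-overlapping with gaps is never what the protocol does
            raise ValueError("step may not exceed window length")

    def count(self, n_samples: int) -> int:
        if n_samples < self.length:
            raise ValueError(
                f"recording of {n_samples} samples is shorter than one "
                f"{self.length}-sample window"
            )
        return (n_samples - self.length) // self.step + 1


#: 5 s window refreshed every 8 samples (nominal 3 Hz at 25.6 Hz sampling)
ONLINE_WINDOW = WindowSpec(length=128, step=8)
#: non-overlapping 25 s windows used by the offline analyses
OFFLINE_WINDOW = WindowSpec(length=640, step=640)


def window_series(data: np.ndarray, spec: WindowSpec):
    """Yield trailing windows (views) of a channels x time array."""
    data = np.asarray(data)
    n = spec.count(data.shape[-1])
    for i in range(n):
        start = i * spec.step
        yield data[..., start:start + spec.length]


def correlation_matrix(window: np.ndarray) -> np.ndarray:
    """Pearson correlation between channels of one window.

    Raises if a channel has zero variance (the correlation is undefined),
    naming the offending channel.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError("window must be channels x samples")
    if window.shape[1] < 3:
        raise ValueError("need at least 3 samples per window")
    sd = window.std(axis=1)
    # constant channels leave rounding-level residuals after centering
    scale = np.maximum(1.0, np.abs(window).max(axis=1))
    dead = np.flatnonzero(sd <= 1e-12 * scale)
    if dead.size:
        raise ValueError(f"zero-variance channel(s): {dead.tolist()}")
    r = np.corrcoef(window)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing Fisher transform Z = arctanh(r).

    |r| is clamped just below 1 so perfectly correlated pairs stay finite.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    return np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))


def edge_count_for_sparsity(n_nodes: int, sparsity: float) -> int:
    """floor(sparsity * n(n-1)/2): never exceed the requested density."""
    return int(np.floor(sparsity * n_nodes * (n_nodes - 1) / 2))


def threshold_binarize(z: np.ndarray, sparsity: float) -> np.ndarray:
    """Binary undirected graph keeping the top |Z| fraction of node pairs.

    The absolute value is ranked (matrix sign convention "Absolute").  Ties
    at the cut are broken deterministically by ascending (row, column) pair
    index so repeated runs build identical graphs.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if z.shape != (n, n):
        raise ValueError("z must be square")
    iu = np.triu_indices(n, 1)
    strength = np.abs(z[iu])
    keep = edge_count_for_sparsity(n, sparsity)
    # stable sort on descending strength == index-order tie-break
    order = np.argsort(-strength, kind="stable")[:keep]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[0][order], iu[1][order]] = True
    return adj | adj.T


def connectivity_graphs(data: np.ndarray, spec: WindowSpec,
                        sparsity: float = 0.3):
    """Full chain: windows -> r -> Z -> thresholded binary graphs.

    Yields (z_matrix, adjacency) per window.
    """
    for win in window_series(data, spec):
        z = fisher_z(correlation_matrix(win))
        yield z, threshold_binarize(z, sparsity)
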