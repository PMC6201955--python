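"""Functional connectivity from population fluorescence traces.

Coherence between neurons is measured as the Pearson correlation of their
fluorescence time series over an analysis window (the stimulation window by
default, since the maps describe activity during stimulation).  The K x K
coherence matrix is thresholded — two neurons are functionally connected
when rho_ij exceeds a fixed threshold, empirically 0.45, optionally also
requiring correlation-test p < 0.05 — giving a binary symmetric adjacency
matrix.  Two graph metrics summarise the network:

- connectivity density ``2m / (K(K-1))``, the fraction of realised edges;
- global efficiency, the mean of inverse shortest-path lengths over ordered
  node pairs (the inverse harmonic mean of path length), a measure of the
  capacity for parallel information transfer.  Disconnected pairs
  contribute zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import shortest_path

from .trace_processing import FluorescenceTrace

__all__ = [
    "CoherenceMatrix",
    "FunctionalGraph",
    "coherence_matrix",
    "threshold_adjacency",
    "connectivity_density",
    "global_efficiency",
    "shortest_path_lengths",
    "graph_metrics",
    "percent",
]


@dataclass
class CoherenceMatrix:
    """Symmetric matrix of pairwise Pearson correlations, diagonal 1."""

    ids: list[str]
    rho: np.ndarray
    n_samples: int
    constant: np.ndarray  # flags traces with zero variance (rho reported 0)

    @property
    def K(self) -> int:
        return len(self.ids)


@dataclass
class FunctionalGraph:
    """Thresholded binary functional-connectivity graph."""

    ids: list[str]
    adjacency: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        self.adjacency = A.astype(np.int8)

    @property
    def K(self) -> int:
        return self.adjacency.shape[0]

    @property
    def m(self) -> int:
        """Number of undirected edges."""
        return int(self.adjacency.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        G = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(G, dict(enumerate(self.ids)))


def coherence_matrix(
    traces: Sequence[FluorescenceTrace],
    window: tuple[float, float] | None = None,
) -> CoherenceMatrix:
    """Pearson correlation between all trace pairs over ``window``.

    rho_ij = sum_t (V_i - mean V_i)(V_j - mean V_j) /
             sqrt(sum_t (V_i - mean V_i)^2 sum_t (V_j - mean V_j)^2)

    Zero-variance (constant) traces have undefined correlations; these are
    reported as 0, flagged, and warned about.
    """
    traces = list(traces)
    if len(traces) < 2:
        raise ValueError("need at least two traces")
    rows = []
    for tr in traces:
        x = tr.samples
        if window is not None:
            times = tr.times
            lo = int(np.searchsorted(times, window[0], side="left"))
            hi = int(np.searchsorted(times, window[1], side="left"))
            x = x[lo:hi]
        rows.append(x)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("traces must have equal length over the window")
    n = lengths.pop()
    if n < 2:
        raise ValueError("window must contain at least two samples")
    V = np.vstack(rows)
    centered = V - V.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant trace(s); their correlations are "
            "undefined and reported as 0",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, norms)
    rho = (centered @ centered.T) / np.outer(safe, safe)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CoherenceMatrix(
        ids=[tr.neuron_id for tr in traces], rho=rho, n_samples=n, constant=constant
    )


def correlation_pvalues(C: CoherenceMatrix) -> np.ndarray:
    """Two-sided p-values of the pairwise correlations (t-test, df = n - 2)."""
    n = C.n_samples
    if n <= 2:
        raise ValueError("need more than two samples for a correlation test")
    r = np.clip(C.rho, -0.9999999999, 0.9999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    return p


def threshold_adjacency(
    C: CoherenceMatrix,
    threshold: float = 0.45,
    require_significance: bool = False,
    alpha: float = 0.05,
) -> FunctionalGraph:
    """Edge iff rho_ij > threshold (and, optionally, correlation p < alpha).

    Only positive correlations above the threshold form edges; the diagonal
    is excluded.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    A = C.rho > threshold
    if require_significance:
        A &= correlation_pvalues(C) < alpha
    np.fill_diagonal(A, False)
    return FunctionalGraph(ids=list(C.ids), adjacency=A.astype(np.int8),
                           threshold=threshold)


def connectivity_density(G: FunctionalGraph) -> float:
    """Fraction of realised edges: ``2m / (K(K-1))``."""
    if G.K < 2:
        raise ValueError("density needs at least two nodes")
    return 2.0 * G.m / (G.K * (G.K - 1))


def shortest_path_lengths(G: FunctionalGraph) -> np.ndarray:
    """Unweighted shortest-path length matrix (inf for disconnected pairs)."""
    return shortest_path(sparse.csr_matrix(G.adjacency), method="D", unweighted=True)


def global_efficiency(G: FunctionalGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    ``E_global = (1 / (K(K-1))) * sum_{i != j} 1 / L_ij`` with
    ``1/L_ij = 0`` for disconnected pairs; 1.0 for a complete graph, 0.0 for
    an edgeless one.
    """
    if G.K < 2:
        raise ValueError("efficiency needs at least two nodes")
    L = shortest_path_lengths(G)
    with np.errstate(divide="ignore"):
        inv = 1.0 / L
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (G.K * (G.K - 1)))


def graph_metrics(G: FunctionalGraph) -> dict[str, float]:
    """Summary dict: K, m, density (fraction and %), global efficiency."""
    density = connectivity_density(G)
    return {
        "K": G.K,
        "m": G.m,
        "threshold": G.threshold,
        "density": density,
        "density_percent": percent(density),
        "global_efficiency": global_efficiency(G),
    }


def percent(fraction: float, decimals: int = 1) -> float:
    """Format a fraction as a percentage truncated to ``decimals`` places.

    Printed percentages in this package truncate rather than round
    (e.g. 0.025633 -> 2.5%), the convention used for the reference values
    the package reproduces.
    """
    scale = 10.0**decimals
    return math.floor(fraction * 100.0 * scale + 1e-12) / scale
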