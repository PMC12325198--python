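"""Density-thresholded binary brain networks and efficiency metrics.

A weighted connectivity matrix is binarized at a fixed connection
density p = 2E / (N^2 - N): the E strongest off-diagonal weights become
edges (round-half-up edge count, ties at the cutoff broken by ascending
(row, column) index), which keeps density constant across trials.

On the resulting undirected binary graph:

* nodal efficiency of node j  = mean over k != j of 1 / d(j, k),
* global efficiency           = mean of nodal efficiencies,
* local efficiency of node i  = mean reciprocal distance within the
  subgraph induced by i's neighbours (0 when fewer than two neighbours).

Distances are hop counts; disconnected pairs contribute 1/inf = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import PLVStack
from .epochs import FeatureTable
from .montage import Montage

__all__ = [
    "BinaryGraph",
    "threshold_by_density",
    "shortest_path_lengths",
    "nodal_efficiency",
    "global_efficiency",
    "local_efficiency",
    "NetworkMetrics",
    "network_metrics",
    "efficiency_table",
]


@dataclass
class BinaryGraph:
    """Undirected binary graph as a symmetric boolean adjacency matrix."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("self-loops are not allowed")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    @property
    def density(self) -> float:
        n = self.n_nodes
        return 2.0 * self.n_edges / (n * n - n)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def threshold_by_density(weights: np.ndarray, p: float = 0.14) -> BinaryGraph:
    """Binarize a symmetric weight matrix at connection density ``p``.

    The edge count is E = round_half_up(p * N(N-1)/2); the E strongest
    upper-triangle weights become edges. Equal weights at the cutoff are
    resolved deterministically by ascending (row, column) order, so the
    realized density is always within one edge of ``p``.
    """
    if not 0 < p <= 1:
        raise ValueError(f"density must be in (0, 1], got {p}")
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if w.ndim != 2 or w.shape[1] != n:
        raise ValueError("weight matrix must be square")
    rows, cols = np.triu_indices(n, k=1)
    m = rows.size
    n_edges = int(np.floor(p * m + 0.5))
    vals = w[rows, cols]
    # primary key: descending weight; ties: ascending row, then column
    order = np.lexsort((cols, rows, -vals))
    pick = order[:n_edges]
    adj = np.zeros((n, n), dtype=bool)
    adj[rows[pick], cols[pick]] = True
    return BinaryGraph(adj | adj.T)


def shortest_path_lengths(g: BinaryGraph) -> np.ndarray:
    """Pairwise hop counts (breadth-first search from every node; inf if disconnected)."""
    if g.n_edges == 0:
        d = np.full((g.n_nodes, g.n_nodes), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return shortest_path(csr_matrix(g.adjacency.astype(np.int8)),
                         method="D", unweighted=True, directed=False)


def _mean_inverse_distance(dist: np.ndarray) -> np.ndarray:
    """Row means of 1/d over off-diagonal entries (1/inf -> 0)."""
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (dist.shape[0] - 1)


def nodal_efficiency(g: BinaryGraph) -> np.ndarray:
    """Per-node mean reciprocal shortest-path length to all other nodes."""
    return _mean_inverse_distance(shortest_path_lengths(g))


def global_efficiency(g: BinaryGraph) -> float:
    """Arithmetic mean of the nodal efficiencies."""
    return float(nodal_efficiency(g).mean())


def local_efficiency(g: BinaryGraph) -> np.ndarray:
    """Efficiency of each node's neighbour-induced subgraph.

    Nodes with fewer than two neighbours get 0 (the normalizer
    N_Gi (N_Gi - 1) is undefined there).
    """
    a = g.adjacency
    out = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = BinaryGraph(a[np.ix_(nbrs, nbrs)])
        out[i] = _mean_inverse_distance(shortest_path_lengths(sub)).mean()
    return out


@dataclass
class NetworkMetrics:
    """Efficiency metrics for a stack of per-trial graphs."""

    nodal: np.ndarray  # (trials, nodes)
    local: np.ndarray  # (trials, nodes)
    global_: np.ndarray  # (trials,)
    labels: np.ndarray
    density: float
    subject_id: str = "unknown"

    @property
    def mean_local(self) -> np.ndarray:
        return self.local.mean(axis=1)


def network_metrics(stack: PLVStack, density: float = 0.14) -> NetworkMetrics:
    """Threshold every trial's PLV matrix and compute the efficiency metrics."""
    n_trials = stack.values.shape[0]
    n_nodes = stack.values.shape[1]
    nodal = np.empty((n_trials, n_nodes))
    local = np.empty((n_trials, n_nodes))
    glob = np.empty(n_trials)
    for t in range(n_trials):
        g = threshold_by_density(stack.values[t], density)
        nodal[t] = nodal_efficiency(g)
        local[t] = local_efficiency(g)
        glob[t] = nodal[t].mean()  # global efficiency is exactly the nodal mean
    return NetworkMetrics(nodal=nodal, local=local, global_=glob,
                          labels=stack.labels, density=density,
                          subject_id=stack.subject_id)


def efficiency_table(metrics: NetworkMetrics, montage: Montage, kind: str) -> FeatureTable:
    """Per-trial nodal or local efficiencies as a classifier feature table."""
    if kind not in ("nodal", "local"):
        raise ValueError("kind must be 'nodal' or 'local'")
    vals = metrics.nodal if kind == "nodal" else metrics.local
    frame = pd.DataFrame(vals, columns=[f"{kind}_{c}" for c in montage.channel_names])
    frame["subject"] = metrics.subject_id
    frame["label"] = list(metrics.labels)
    keep = frame["label"].isin(["positive", "negative"])
    return FeatureTable(frame[keep].reset_index(drop=True))
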