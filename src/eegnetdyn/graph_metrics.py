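"""Weighted graph measures of averaged stable networks.

Correlation weights are mapped to connection lengths by ``length = 1/w``
(after taking absolute values), shortest paths are computed over lengths,
and the six summary measures are derived from the distance matrix and the
weighted triangle structure:

* eccentricity of node *i* = max over *j* of shortest-path distance;
  diameter = max eccentricity, radius = min eccentricity;
* characteristic path length = mean finite off-diagonal distance;
* global efficiency = mean inverse distance (0 for unreachable pairs);
* weighted transitivity = geometric-mean triangle intensity relative to the
  number of connected triples;
* maximum modularity = best Newman Q over seeded Louvain restarts.

Disconnected graphs propagate infinite eccentricities (flagged, never
silently restricted to the largest component).
"""

from __future__ import annotations

import warnings
from typing import Optional

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .datatypes import ConnectivityMatrix, NetworkMetrics, as_weights

__all__ = [
    "weight_to_length",
    "path_metrics",
    "transitivity",
    "max_modularity",
    "compute_metrics",
]


def _nonneg_weights(W, negatives: str = "abs") -> np.ndarray:
    """Weights made non-negative: absolute value (default) or clip at 0."""
    W = as_weights(W).copy()
    if negatives == "abs":
        W = np.abs(W)
    elif negatives == "clip":
        W = np.clip(W, 0.0, None)
    else:
        raise ValueError(f"unknown negatives policy {negatives!r}")
    np.fill_diagonal(W, 0.0)
    return W


def weight_to_length(W) -> np.ndarray:
    """Connection lengths ``1/w`` (infinite where ``w == 0``), zero diagonal."""
    W = _nonneg_weights(W)
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def _distance_matrix(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances over connection lengths."""
    L = weight_to_length(W)
    n = L.shape[0]
    finite = np.isfinite(L) & (L > 0)
    graph = csr_array((L[finite], np.nonzero(finite)), shape=(n, n))
    return shortest_path(graph, method="D", directed=False)


def path_metrics(W) -> tuple[float, float, float, float]:
    """``(char_path_length, diameter, radius, global_efficiency)``.

    Computed from the shortest-path distance matrix over 1/w lengths.  On a
    disconnected graph the diameter and radius are infinite and a structured
    warning is emitted; characteristic path length averages the finite
    off-diagonal distances only and unreachable pairs contribute zero
    efficiency.
    """
    W = _nonneg_weights(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    D = _distance_matrix(W)
    off = ~np.eye(n, dtype=bool)
    ecc = D.max(axis=1)
    diameter = float(ecc.max())
    radius = float(ecc.min())
    if not np.isfinite(diameter):
        warnings.warn("graph is disconnected; diameter/radius are infinite", stacklevel=2)
    finite_off = off & np.isfinite(D)
    cpl = float(D[finite_off].mean()) if finite_off.any() else np.inf
    with np.errstate(divide="ignore"):
        inv = np.where(D[off] > 0, 1.0 / D[off], 0.0)
    efficiency = float(np.where(np.isfinite(D[off]), inv, 0.0).mean())
    return cpl, diameter, radius, efficiency


def transitivity(W) -> float:
    """Weighted transitivity: twice the geometric-mean triangle intensity
    summed over nodes, divided by the number of connected triples
    ``sum_i k_i (k_i - 1)`` with ``k`` the binary degree.  0 when the graph
    has no connected triples."""
    W = _nonneg_weights(W)
    cube_root = np.cbrt(W)
    cyc3 = np.diag(cube_root @ cube_root @ cube_root)  # 2 × triangle intensity per node
    k = (W > 0).sum(axis=1)
    denom = float((k * (k - 1)).sum())
    if denom == 0:
        return 0.0
    return float(cyc3.sum() / denom)


def max_modularity(
    W,
    n_restarts: int = 100,
    seed: int = 0,
) -> tuple[float, list[set[int]]]:
    """Best Newman modularity Q over seeded Louvain restarts (γ = 1).

    The all-in-one partition (Q = 0) is always included as a candidate, so
    the returned Q is never below it.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    W = _nonneg_weights(W)
    n = W.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    G = nx.from_numpy_array(W)
    best_part: list[set[int]] = [set(range(n))]
    if G.number_of_edges() == 0:
        return 0.0, best_part
    best_q = nx.community.modularity(G, best_part, weight="weight")
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        part = nx.community.louvain_communities(
            G, weight="weight", seed=int(rng.integers(2**31))
        )
        q = nx.community.modularity(G, part, weight="weight")
        if q > best_q:
            best_q, best_part = q, [set(c) for c in part]
    return float(best_q), best_part


def compute_metrics(
    W: "ConnectivityMatrix | np.ndarray",
    n_restarts: int = 100,
    seed: int = 0,
) -> NetworkMetrics:
    """All six measures of one averaged stable network."""
    cpl, diameter, radius, efficiency = path_metrics(W)
    q, _ = max_modularity(W, n_restarts=n_restarts, seed=seed)
    return NetworkMetrics(
        diameter=diameter,
        radius=radius,
        char_path_length=cpl,
        transitivity=transitivity(W),
        max_modularity=q,
        global_efficiency=efficiency,
        disconnected=not np.isfinite(diameter),
    )
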