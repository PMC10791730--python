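"""Weighted graph-theory metrics for structural brain networks.

All metrics operate on weights scaled by the mean of the surviving
connection weights, so every subject's network carries the same total
"cost" and between-subject differences reflect topology rather than
overall connection strength.  Path lengths use the reciprocal of the
scaled weight as the edge length (a stronger connection is a shorter
route), computed with Dijkstra's algorithm.

Definitions
-----------
* nodal clustering  ``C_i = 2/(k_i (k_i - 1)) * sum_{j<k} (w~_ij w~_jk w~_ki)^(1/3)``
  (geometric-mean triangle intensity; nodes with degree < 2 contribute 0)
* clustering coefficient ``Cp = mean_i C_i``
* characteristic path length ``Lp = mean over ordered pairs of L_ij``
* global efficiency ``Eglob = mean over ordered pairs of 1/L_ij`` (1/inf := 0)
* local efficiency ``Eloc = mean_i Eglob(G_i)`` where ``G_i`` is the subgraph
  induced on the neighbors of *i* (their mutual scaled weights)
* nodal efficiency ``Enodal(i) = mean_{j != i} 1/L_ij``

``mean(Enodal) == Eglob`` holds identically and is asserted in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .errors import EmptyNetworkError
from .types import as_weights
from .errors import DisconnectedNetworkWarning


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class ScaledMatrix:
    """Weights divided by the mean nonzero weight (mean of scaled entries = 1)."""

    scaled_weights: np.ndarray
    scale_factor: float


@dataclass(frozen=True)
class NodalClusteringVector:
    c: np.ndarray
    degrees: np.ndarray


@dataclass(frozen=True)
class GlobalMetricsRecord:
    Cp: float
    Lp: float
    Eglob: float
    Eloc: float
    subject_id: str | None = None
    sparsity: float | None = None
    disconnected: bool = False


@dataclass(frozen=True)
class NodalEfficiencyVector:
    e: np.ndarray
    subject_id: str | None = None
    sparsity: float | None = None


# ---------------------------------------------------------------------------
# scaling

def scale_weights(network) -> ScaledMatrix:
    """Divide every weight by the mean of the nonzero weights.

    Each undirected edge counts once in the mean, so the nonzero entries of
    the result average exactly 1.
    """
    w = as_weights(network)
    iu = np.triu_indices(w.shape[0], 1)
    vals = w[iu]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise EmptyNetworkError("cannot scale an edgeless network")
    factor = float(vals.mean())
    return ScaledMatrix(scaled_weights=w / factor, scale_factor=factor)


# ---------------------------------------------------------------------------
# clustering

def clustering(network) -> tuple[NodalClusteringVector, float]:
    """Weighted nodal clustering (geometric triangle mean) and its average Cp.

    Accepts a raw/thresholded network (scaling applied internally) or a
    :class:`ScaledMatrix`.
    """
    scaled = network if isinstance(network, ScaledMatrix) else scale_weights(network)
    W = scaled.scaled_weights
    k = (W > 0).sum(axis=1).astype(float)
    W13 = np.cbrt(W)
    # diag((W^{1/3})^3)_i counts ordered neighbor pairs, i.e. 2 * unordered sum
    t = np.diagonal(W13 @ W13 @ W13).copy()
    denom = np.where(k >= 2, k * (k - 1), 1.0)
    c = np.where(k >= 2, t / denom, 0.0)
    return NodalClusteringVector(c=c, degrees=k.astype(int)), float(c.mean())


# ---------------------------------------------------------------------------
# shortest paths and efficiencies

def shortest_paths(network) -> np.ndarray:
    """All-pairs shortest path lengths with edge length ``1 / w~_ij``.

    Unreachable pairs are ``inf``; the diagonal is 0.
    """
    scaled = network if isinstance(network, ScaledMatrix) else scale_weights(network)
    W = scaled.scaled_weights
    lengths = np.zeros_like(W)
    mask = W > 0
    lengths[mask] = 1.0 / W[mask]
    return dijkstra(csr_array(lengths), directed=False)


def characteristic_path_length(paths: np.ndarray) -> tuple[float, bool]:
    """Mean shortest path length over ordered pairs.

    Infinite (disconnected) pairs are excluded from the mean and flagged by
    the returned boolean; propagating infinity would make Lp useless at
    low sparsity.
    """
    n = paths.shape[0]
    if n < 2:
        raise EmptyNetworkError("Lp requires at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    vals = paths[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise EmptyNetworkError("no finite node pair; network has no edges")
    disconnected = not finite.all()
    if disconnected:
        warnings.warn(
            "network has unreachable node pairs; Lp computed over finite pairs",
            DisconnectedNetworkWarning,
            stacklevel=2,
        )
    return float(vals[finite].mean()), disconnected


def global_efficiency(paths: np.ndarray) -> float:
    """Mean inverse shortest path length over ordered pairs (1/inf := 0)."""
    n = paths.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    vals = paths[off]
    inv = np.zeros_like(vals)
    finite = np.isfinite(vals) & (vals > 0)
    inv[finite] = 1.0 / vals[finite]
    return float(inv.mean())


def nodal_efficiency(paths: np.ndarray, subject_id=None, sparsity=None) -> NodalEfficiencyVector:
    """Per-node mean inverse shortest path length to the other N-1 nodes."""
    n = paths.shape[0]
    inv = np.zeros_like(paths)
    finite = np.isfinite(paths) & (paths > 0)
    inv[finite] = 1.0 / paths[finite]
    e = inv.sum(axis=1) / max(n - 1, 1)
    return NodalEfficiencyVector(e=e, subject_id=subject_id, sparsity=sparsity)


@njit(cache=False)
def _floyd_warshall_inplace(D):  # pragma: no cover - exercised via local_efficiency
    n = D.shape[0]
    for k in range(n):
        for i in range(n):
            dik = D[i, k]
            if dik == np.inf:
                continue
            for j in range(n):
                d = dik + D[k, j]
                if d < D[i, j]:
                    D[i, j] = d


@njit(cache=False)
def _local_efficiency_kernel(W):  # pragma: no cover - exercised via local_efficiency
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        nbr = np.where(W[i] > 0)[0]
        m = nbr.size
        if m < 2:
            continue
        D = np.empty((m, m))
        for a in range(m):
            D[a, a] = 0.0
            for b in range(m):
                if a == b:
                    continue
                w = W[nbr[a], nbr[b]]
                D[a, b] = 1.0 / w if w > 0 else np.inf
        _floyd_warshall_inplace(D)
        s = 0.0
        for a in range(m):
            for b in range(m):
                if a != b and D[a, b] != np.inf and D[a, b] > 0:
                    s += 1.0 / D[a, b]
        total += s / (m * (m - 1))
    return total / n


def local_efficiency(network) -> float:
    """Mean, over nodes, of the global efficiency of the neighbor subgraph.

    The neighbor subgraph of node *i* keeps the mutual scaled weights of
    *i*'s neighbors (node *i* itself is removed); a subgraph with fewer
    than 2 nodes contributes 0.
    """
    scaled = network if isinstance(network, ScaledMatrix) else scale_weights(network)
    return float(_local_efficiency_kernel(np.ascontiguousarray(scaled.scaled_weights)))


# ---------------------------------------------------------------------------
# per-network summary

def compute_global_metrics(network, subject_id=None, sparsity=None) -> GlobalMetricsRecord:
    """Cp, Lp, Eglob and Eloc of one (thresholded) network."""
    scaled = scale_weights(network)
    _, cp = clustering(scaled)
    paths = shortest_paths(scaled)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DisconnectedNetworkWarning)
        lp, disconnected = characteristic_path_length(paths)
    if sparsity is None and hasattr(network, "sparsity"):
        sparsity = network.sparsity
    return GlobalMetricsRecord(
        Cp=cp,
        Lp=lp,
        Eglob=global_efficiency(paths),
        Eloc=local_efficiency(scaled),
        subject_id=subject_id,
        sparsity=sparsity,
        disconnected=disconnected,
    )
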