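"""Weighted graph statistics on partial-correlation or correlation networks.

Distances between connected nodes are Omega = 1 - |theta|; node statistics
are the weighted characteristic path length L_i (mean shortest distance to
all reachable nodes), the Onnela weighted clustering coefficient
C_i = 2 t_i / (k_i (k_i - 1)) with t_i the geometric-mean triangle intensity
under max-normalised weights, and their ratio, the small-world coefficient
S_i = C_i / L_i (no random-network normalisation).  Non-edges contribute no
direct link — they are unreachable, not at distance 1.  Unreachable pairs are
excluded from L_i; isolated nodes get NaN and are dropped from group
statistics downstream.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import csgraph_from_dense, dijkstra

from .dataset import split_node_name
from .exceptions import DomainError, SchemaError
from .ggm import GGMResult
from .pearson import PearsonNetwork

METRIC_NAMES = ("clustering", "path_length", "small_world")


def network_matrices(result) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(theta, adjacency, node names) for a GGM result or a Pearson network."""
    if isinstance(result, GGMResult):
        return result.partial_corr, result.adjacency, list(result.node_names)
    if isinstance(result, PearsonNetwork):
        return result.weighted(), result.mask, list(result.node_names)
    raise SchemaError(f"unsupported network object {type(result).__name__}")


def to_distance(theta: np.ndarray, adjacency: np.ndarray | None = None) -> np.ndarray:
    """Omega = 1 - |theta|; zero diagonal; non-edges set to +inf (no link)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(np.abs(theta) > 1.0 + 1e-12):
        raise DomainError("|theta| exceeds 1")
    if adjacency is None:
        adjacency = (theta != 0).astype(int)
        np.fill_diagonal(adjacency, 0)
    omega = 1.0 - np.abs(theta)
    omega[~adjacency.astype(bool)] = np.inf
    np.fill_diagonal(omega, 0.0)
    return omega


def path_length(omega: np.ndarray, adjacency: np.ndarray | None = None) -> np.ndarray:
    """L_i: mean Dijkstra distance from i to every reachable node (NaN if none)."""
    omega = np.asarray(omega, dtype=float)
    if adjacency is not None:
        omega = omega.copy()
        omega[~np.asarray(adjacency).astype(bool)] = np.inf
        np.fill_diagonal(omega, 0.0)
    finite = omega[np.isfinite(omega)]
    if np.any(finite < 0):
        raise DomainError("negative edge distance")
    graph = csgraph_from_dense(omega, null_value=np.inf)
    dist = dijkstra(graph, directed=False)
    P = omega.shape[0]
    L = np.full(P, np.nan)
    for i in range(P):
        d = np.delete(dist[i], i)
        reachable = np.isfinite(d)
        if reachable.any():
            L[i] = d[reachable].mean()
    return L


def reachable_counts(omega: np.ndarray) -> np.ndarray:
    graph = csgraph_from_dense(np.asarray(omega, dtype=float), null_value=np.inf)
    dist = dijkstra(graph, directed=False)
    np.fill_diagonal(dist, np.inf)
    return np.isfinite(dist).sum(axis=1)


def clustering(theta: np.ndarray, adjacency: np.ndarray | None = None) -> np.ndarray:
    """Onnela weighted clustering: C_i = 2 t_i / (k_i (k_i - 1)).

    Connection weights are |theta| divided by the maximum |theta| over present
    edges; t_i = 0.5 * sum_{j,h} (w_ij w_ih w_jh)^(1/3).  C_i = 0 for nodes of
    degree < 2.
    """
    theta = np.asarray(theta, dtype=float)
    if adjacency is None:
        adjacency = (theta != 0).astype(int)
        np.fill_diagonal(adjacency, 0)
    adjacency = np.asarray(adjacency).astype(bool)
    w = np.abs(theta) * adjacency
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    k = adjacency.sum(axis=1)
    C = np.zeros(theta.shape[0])
    if wmax == 0:
        return C
    cube = np.cbrt(w / wmax)
    t = np.einsum("ij,jh,hi->i", cube, cube, cube) / 2.0
    valid = k >= 2
    C[valid] = 2.0 * t[valid] / (k[valid] * (k[valid] - 1.0))
    return C


def small_world(C: np.ndarray, L: np.ndarray) -> np.ndarray:
    """S_i = C_i / L_i; NaN where L_i is undefined."""
    C = np.asarray(C, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(L[np.isfinite(L)] <= 0):
        raise DomainError("path length must be positive (|theta| = 1 edges collapse distance)")
    S = np.full_like(C, np.nan)
    ok = np.isfinite(L)
    S[ok] = C[ok] / L[ok]
    return S


def node_metrics(
    theta: np.ndarray,
    adjacency: np.ndarray,
    node_names: Sequence[str],
) -> pd.DataFrame:
    """Tidy per-node table: degree, clustering, path length, small-world."""
    adjacency = np.asarray(adjacency).astype(int)
    omega = to_distance(theta, adjacency)
    L = path_length(omega)
    C = clustering(theta, adjacency)
    S = small_world(C, L)
    return pd.DataFrame(
        {
            "node": list(node_names),
            "degree": adjacency.sum(axis=1),
            "clustering": C,
            "path_length": L,
            "small_world": S,
            "reachable_count": reachable_counts(omega),
        }
    )


def modality_block_metrics(result, modality: str) -> pd.DataFrame:
    """Node metrics on the within-modality subgraph.

    Extracts the sub-matrix of nodes tagged with ``modality`` and computes all
    metrics on that subgraph (inter-modal edges are excluded entirely).
    """
    theta, adjacency, names = network_matrices(result)
    labels = [split_node_name(n) for n in names]
    idx = [k for k, (_, m) in enumerate(labels) if m == modality]
    if not idx:
        known = sorted({m for _, m in labels})
        raise SchemaError(f"unknown modality {modality!r}; have {known}")
    sub = np.ix_(idx, idx)
    table = node_metrics(theta[sub], adjacency[sub], [names[k] for k in idx])
    table.insert(0, "modality", modality)
    table.insert(1, "region", [labels[k][0] for k in idx])
    return table


def metrics_table(results_by_group: dict, modalities: Sequence[str]) -> pd.DataFrame:
    """Stacked per-group, per-modality-block node metrics (tidy TSV layout)."""
    frames = []
    for group, result in results_by_group.items():
        for modality in modalities:
            block = modality_block_metrics(result, modality)
            block.insert(0, "group", group)
            frames.append(block)
    return pd.concat(frames, ignore_index=True)
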