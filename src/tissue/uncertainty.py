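"""Spatial neighbourhood graph and the cell-centric variability measure.

Cell-centric variability is the package's model-agnostic first-pass
uncertainty: for cell i and gene j,

    U_ij = 1 + sum_{k in N_i} W_ik (Xhat_kj - Xhat_ij)^2 / sum_{k in N_i} W_ik

where N_i are the K nearest cells of i in physical space and
W_ik = exp(cos(Xhat_i, Xhat_k)) is an exponential cosine similarity of the
*predicted* expression profiles, so deviation from transcriptionally similar
neighbours (same cell type) counts more than deviation from dissimilar ones.
The +1 intercept keeps calibration scores well-defined when a neighbourhood
is expression-constant. U >= 1 always.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .core_data import PredictionMatrix

__all__ = [
    "NeighborhoodGraph",
    "WeightMatrix",
    "VariabilityMatrix",
    "build_graph",
    "graph_from_edge_list",
    "compute_weights",
    "cell_centric_variability",
    "variability_from_coords",
]


@dataclass
class NeighborhoodGraph:
    """Pruned K-nearest-neighbour graph over cell coordinates.

    ``neighbors[i]`` / ``distances[i]`` are parallel arrays. No cell is its
    own neighbour, every cell keeps at least one neighbour, and all retained
    distances are <= ``pruning_threshold`` except the single forced nearest
    neighbour of a fully pruned (outlier) cell.
    """

    neighbors: list[np.ndarray]
    distances: list[np.ndarray]
    K: int
    pruning_threshold: float

    @property
    def n_cells(self) -> int:
        return len(self.neighbors)


@dataclass
class WeightMatrix:
    """Exponential-cosine edge weights, sparse on the graph edges."""

    matrix: sp.csr_matrix  # n_cells x n_cells, entries in [e^-1, e]


@dataclass
class VariabilityMatrix:
    """Cell-centric variability U (cells x genes), entries >= 1."""

    values: np.ndarray
    graph_ref: str = ""


def build_graph(coords: np.ndarray, K: int = 15) -> NeighborhoodGraph:
    """Link each cell to its min(K, n-1) nearest cells, then prune outliers.

    Edges longer than Q3 + 1.5 (Q3 - Q1) of the pooled neighbour-distance
    distribution are removed; a cell that loses every edge keeps its single
    nearest neighbour so the graph never has an isolated cell. Distance ties
    at the K-th neighbour break toward the lower cell index.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to build a neighbourhood graph")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    k_eff = min(K, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # drop self (distance 0 to itself; under exact duplicates sklearn may
    # order ties arbitrarily, so remove "self" explicitly and re-sort by
    # (distance, index) for deterministic tie-breaks)
    neighbors, distances, pooled = [], [], []
    for i in range(n):
        mask = idx[i] != i
        di, ni = dist[i][mask][:k_eff], idx[i][mask][:k_eff]
        order = np.lexsort((ni, di))
        neighbors.append(ni[order])
        distances.append(di[order])
        pooled.append(di)
    pooled = np.concatenate(pooled)
    q1, q3 = np.percentile(pooled, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    for i in range(n):
        keep = distances[i] <= fence
        if not keep.any():
            keep = np.zeros_like(keep)
            keep[0] = True  # forced single nearest neighbour
        neighbors[i] = neighbors[i][keep]
        distances[i] = distances[i][keep]
    return NeighborhoodGraph(neighbors, distances, K, float(fence))


def graph_from_edge_list(
    path: str | Path, cell_ids: list[str]
) -> tuple[NeighborhoodGraph, WeightMatrix]:
    """Load a user-supplied adjacency (cell_id, cell_id, weight) as the graph.

    Replaces both the built-in spatial graph and the cosine weights, e.g. to
    use an externally de-noised cell-similarity graph. Self-edges are dropped.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    index = {c: i for i, c in enumerate(cell_ids)}
    n = len(cell_ids)
    rows, cols, w = [], [], []
    for a, b, weight in df.itertuples(index=False):
        ia, ib = index[str(a)], index[str(b)]
        if ia == ib:
            continue
        rows.append(ia)
        cols.append(ib)
        w.append(float(weight))
    W = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    neighbors = [W.indices[W.indptr[i] : W.indptr[i + 1]].copy() for i in range(n)]
    if any(len(nb) == 0 for nb in neighbors):
        raise ValueError("every cell needs at least one edge in the adjacency")
    dists = [np.zeros(len(nb)) for nb in neighbors]
    graph = NeighborhoodGraph(neighbors, dists, K=0, pruning_threshold=np.inf)
    return graph, WeightMatrix(W)


def compute_weights(pred: PredictionMatrix, graph: NeighborhoodGraph) -> WeightMatrix:
    """W_ik = exp(cosine(Xhat_i, Xhat_k)) on graph edges.

    The cosine uses all genes present in ``pred``; a zero-norm profile has
    cosine 0 by convention, hence weight exp(0) = 1.
    """
    X = pred.values
    if X.shape[0] != graph.n_cells:
        raise ValueError("prediction matrix does not cover the graph's cells")
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    Xn = X / safe[:, None]
    Xn[norms == 0] = 0.0
    rows = np.repeat(
        np.arange(graph.n_cells), [len(nb) for nb in graph.neighbors]
    )
    cols = np.concatenate(graph.neighbors) if graph.n_cells else np.array([], int)
    cos = np.einsum("ij,ij->i", Xn[rows], Xn[cols])
    W = sp.csr_matrix(
        (np.exp(cos), (rows, cols)), shape=(graph.n_cells, graph.n_cells)
    )
    return WeightMatrix(W)


def cell_centric_variability(
    pred: PredictionMatrix,
    graph: NeighborhoodGraph,
    weights: WeightMatrix | None = None,
) -> VariabilityMatrix:
    """Evaluate U for every cell and gene in ``pred``.

    Vectorised through the sparse weight matrix:
    sum_k W_ik (x_k - x_i)^2 = (W x^2)_i - 2 x_i (W x)_i + x_i^2 (W 1)_i.
    """
    if weights is None:
        weights = compute_weights(pred, graph)
    W = weights.matrix
    X = pred.values
    if X.shape[0] != W.shape[0]:
        raise ValueError("prediction matrix does not cover the graph's cells")
    wsum = np.asarray(W.sum(axis=1)).ravel()
    if np.any(wsum <= 0):
        raise ValueError("a cell has zero total neighbour weight")
    num = W @ (X**2) - 2.0 * X * (W @ X) + (X**2) * wsum[:, None]
    num = np.maximum(num, 0.0)  # guard float cancellation
    U = 1.0 + num / wsum[:, None]
    return VariabilityMatrix(U, graph_ref=f"knn(K={graph.K})")


def variability_from_coords(
    pred: PredictionMatrix, coords: np.ndarray, K: int = 15
) -> tuple[NeighborhoodGraph, WeightMatrix, VariabilityMatrix]:
    """Convenience: graph + weights + U in one call."""
    graph = build_graph(coords, K=K)
    weights = compute_weights(pred, graph)
    return graph, weights, cell_centric_variability(pred, graph, weights)
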