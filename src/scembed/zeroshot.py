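"""Zero-shot tasks on cell embeddings.

No training is involved: cells are compared directly in the aggregated
embedding space. This module provides the exact k-nearest-neighbor graph the
downstream metrics share, Leiden community detection on that graph,
majority-vote kNN label transfer (k = 10 by default), and projection-based
batch integration (each batch aggregated independently over the shared
feature set, then concatenated — no trainable alignment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .aggregate import cell_embeddings
from .data import CellEmbeddingMatrix, ExpressionMatrix, FeatureEmbeddingTable, ValidationError

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "cosine")


@dataclass
class NeighborGraph:
    """Exact kNN lists per cell, sorted ascending by distance, self excluded."""

    k: int
    indices: np.ndarray  # (n, k) int
    distances: np.ndarray  # (n, k) float
    metric: str = "euclidean"

    @property
    def n(self) -> int:
        return self.indices.shape[0]

    def edges(self):
        """Undirected edge set (i < j) of the kNN graph."""
        rows = np.repeat(np.arange(self.n), self.indices.shape[1])
        cols = self.indices.ravel()
        lo, hi = np.minimum(rows, cols), np.maximum(rows, cols)
        return np.unique(np.stack([lo, hi], axis=1), axis=0)


def _as_array(emb) -> np.ndarray:
    if isinstance(emb, CellEmbeddingMatrix):
        return emb.vectors
    return np.asarray(emb, dtype=float)


def knn_graph(emb, k: int, metric: str = "euclidean") -> NeighborGraph:
    """Exact k nearest neighbors; ties broken by lower cell index."""
    X = _as_array(emb)
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 cells for a neighbor graph")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}")
    if k >= n:
        logger.warning("k=%d >= n=%d; clipping to %d", k, n, n - 1)
        k = n - 1
    D = cdist(X, X, metric=metric)
    np.fill_diagonal(D, np.inf)
    idx = np.arange(n)
    order = np.lexsort((np.broadcast_to(idx, (n, n)), D), axis=1)[:, :k]
    dist = np.take_along_axis(D, order, axis=1)
    return NeighborGraph(k=k, indices=order, distances=dist, metric=metric)


def cluster_cells(
    emb, k: int = 15, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden community detection on the kNN graph (modularity-style).

    Deterministic for a fixed seed; labels are consecutive integers from 0.
    """
    import igraph
    import leidenalg

    X = _as_array(emb)
    n = X.shape[0]
    if n == 1:
        return np.array([0])
    g = knn_graph(X, k)
    graph = igraph.Graph(n=n, edges=[tuple(e) for e in g.edges()], directed=False)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # relabel to consecutive ids in order of first appearance
    _, first = np.unique(labels, return_index=True)
    remap = {labels[i]: r for r, i in enumerate(sorted(first))}
    return np.array([remap[l] for l in labels])


def knn_annotate(
    train: CellEmbeddingMatrix,
    train_labels,
    test: CellEmbeddingMatrix,
    k: int = 10,
    metric: str = "euclidean",
):
    """Majority-vote kNN label transfer with k = 10 by default.

    Returns ``(labels, vote_fractions)``; ties are broken by the label of
    the nearest neighbor among the tied labels.
    """
    Xtr, Xte = _as_array(train), _as_array(test)
    train_labels = [str(l) for l in train_labels]
    if Xtr.shape[0] == 0:
        raise ValidationError("empty training set")
    if len(train_labels) != Xtr.shape[0]:
        raise ValidationError("one label per training cell required")
    if k > Xtr.shape[0]:
        logger.warning("k=%d > train size %d; clipping", k, Xtr.shape[0])
        k = Xtr.shape[0]
    D = cdist(Xte, Xtr, metric=metric)
    idx = np.arange(Xtr.shape[0])
    order = np.lexsort((np.broadcast_to(idx, D.shape), D), axis=1)[:, :k]
    preds, fracs = [], []
    for row in order:
        votes: dict[str, int] = {}
        for j in row:
            votes[train_labels[j]] = votes.get(train_labels[j], 0) + 1
        top = max(votes.values())
        tied = {l for l, c in votes.items() if c == top}
        if len(tied) == 1:
            (winner,) = tied
        else:
            winner = next(train_labels[j] for j in row if train_labels[j] in tied)
        preds.append(winner)
        fracs.append(top / k)
    return np.array(preds, dtype=object), np.array(fracs)


def project_batches(
    batches: list[ExpressionMatrix],
    feats: FeatureEmbeddingTable,
    mode: str = "wa",
    batch_names: list[str] | None = None,
):
    """Project every batch into the shared embedding space, no training.

    Features are intersected by name across all batches and the embedding
    table; each batch is aggregated independently with the identical feature
    order, then the rows are concatenated. Returns ``(CellEmbeddingMatrix,
    batch_labels)``.
    """
    if len(batches) < 2:
        raise ValidationError("need at least 2 batches")
    batch_names = batch_names or [f"batch{i}" for i in range(len(batches))]
    shared = [f for f in batches[0].feature_ids if f in set(feats.names)]
    for i, b in enumerate(batches[1:], start=1):
        have = set(b.feature_ids)
        shared = [f for f in shared if f in have]
        if not shared:
            raise ValidationError(
                f"empty feature intersection between batch 0 and batch {i}"
            )
    parts, labels, ids = [], [], []
    for name, b in zip(batch_names, batches):
        e = cell_embeddings(b.subset_features(shared), feats, mode)
        parts.append(e.vectors)
        labels.extend([name] * e.n_cells)
        ids.extend(f"{name}:{c}" for c in e.cell_ids)
    return CellEmbeddingMatrix(ids, np.vstack(parts)), np.array(labels, dtype=object)
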