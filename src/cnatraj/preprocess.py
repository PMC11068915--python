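"""Depth normalisation, pluggable embedding, and kNN graph construction.

These are the substrate the genotype-mixing score and reference mapping
operate on. The embedding is a contract (any callable producing a
cells x d matrix); the default is PCA on centred log-normalised data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import anndata as ad
import numpy as np
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances_chunked

__all__ = ["Embedding", "NeighborGraph", "normalize_log1p", "embed", "knn_graph"]


@dataclass
class Embedding:
    """A cells x d real-valued reduction with a method tag."""

    coordinates: np.ndarray
    method_tag: str
    d: int

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding contains non-finite values")
        if self.coordinates.shape[1] != self.d:
            raise ValueError("embedding width does not match d")


@dataclass
class NeighborGraph:
    """K nearest neighbours per cell (self excluded), row-aligned to cells."""

    neighbor_indices: np.ndarray
    K: int
    distance_metric: str = "euclidean"

    def __post_init__(self) -> None:
        idx = np.asarray(self.neighbor_indices)
        n = idx.shape[0]
        if idx.shape[1] != self.K:
            raise ValueError("neighbor_indices width does not match K")
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError("neighbor indices out of range")
        self.neighbor_indices = idx.astype(np.int64)


def _dense(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def normalize_log1p(counts: ad.AnnData) -> ad.AnnData:
    """Scale each cell to the median total count, then log1p.

    Raises if any cell has zero total counts (names the first offenders).
    Raw counts are preserved in ``layers['counts']``.
    """
    import scanpy as sc

    X = counts.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = list(np.asarray(counts.obs_names)[totals == 0][:5])
        raise ValueError(f"cells with zero total counts: {bad}")
    out = counts.copy()
    out.layers["counts"] = out.X.copy()
    sc.pp.normalize_total(out, target_sum=None)
    sc.pp.log1p(out)
    return out


def embed(
    norm: ad.AnnData | np.ndarray,
    d: int = 10,
    method: str | Callable[[np.ndarray, int], np.ndarray] = "pca",
    random_state: int = 0,
) -> Embedding:
    """Reduce a normalised matrix to ``d`` dimensions.

    Default method is PCA on centred data; any callable
    ``(matrix, d) -> cells x d array`` may be plugged in instead.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    X = _dense(norm.X) if isinstance(norm, ad.AnnData) else _dense(norm)
    if d > min(X.shape):
        raise ValueError("d must not exceed min(cells, genes)")
    if callable(method):
        coords = np.asarray(method(X, d), dtype=float)
        return Embedding(coords, getattr(method, "__name__", "custom"), d)
    if method != "pca":
        raise ValueError(f"unknown embedding method {method!r}")
    pca = PCA(n_components=d, svd_solver="full" if min(X.shape) <= 1000 else "randomized",
              random_state=random_state)
    coords = pca.fit_transform(X)
    return Embedding(coords, "pca", d)


def knn_graph(emb: Embedding | np.ndarray, K: int, include_self: bool = False) -> NeighborGraph:
    """Exact K nearest neighbours (Euclidean), ties broken by cell index.

    Self is excluded by index (not by zero distance), so duplicated points
    are each other's nearest neighbour.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    X = emb.coordinates if isinstance(emb, Embedding) else np.asarray(emb, dtype=float)
    n = X.shape[0]
    limit = n if include_self else n - 1
    if K > limit:
        raise ValueError(f"K={K} too large for {n} cells")
    out = np.empty((n, K), dtype=np.int64)
    row0 = 0
    idx_all = np.arange(n)
    for chunk in pairwise_distances_chunked(X, metric="euclidean", working_memory=64):
        for i in range(chunk.shape[0]):
            dist = chunk[i]
            cell = row0 + i
            if include_self:
                cand = idx_all
                d = dist
            else:
                cand = np.concatenate([idx_all[:cell], idx_all[cell + 1:]])
                d = np.concatenate([dist[:cell], dist[cell + 1:]])
            order = np.lexsort((cand, d))  # distance first, index breaks ties
            out[cell] = cand[order[:K]]
        row0 += chunk.shape[0]
    return NeighborGraph(out, K, "euclidean")
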