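"""Normalization, embedding and graph clustering of count matrices.

The workflow mirrors the standard single-cell dialect: per-cell depth
normalization to a fixed scale factor followed by log1p, highly variable
gene selection by standardized (vst-style) variance of the raw counts,
scaled-and-clipped PCA, a Jaccard-weighted shared-nearest-neighbor graph,
and modularity clustering (Leiden) at a user-chosen resolution — the one
free parameter of the analysis.  Clusters are validated by silhouette
scores in the embedding space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ClusterResult",
    "normalize_log1p",
    "select_hvg",
    "pca_embed",
    "cluster_graph",
    "silhouette_by_cluster",
]

SNN_PRUNE = 1 / 15  # drop SNN edges with Jaccard weight below this


@dataclass
class ClusterResult:
    """Graph-clustering output: labels (renumbered by decreasing size),
    the resolution that produced them and optional per-cluster silhouettes."""

    labels: np.ndarray
    resolution: float
    n_clusters: int
    silhouette_per_cluster: dict[int, float] | None = None
    embedding: np.ndarray | None = None

    def sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()


def normalize_log1p(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Depth-normalize to ``scale_factor`` counts per cell, then log1p.

    Returns a new AnnData with normalized values in ``X`` and the raw counts
    preserved in ``layers['counts']``.  Cells with zero counts must be
    removed upstream (see :mod:`organovasc.qc`).
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("cells with zero total counts; run qc_filter first")
    scaled = sp.diags(scale_factor / totals) @ X
    scaled.data = np.log1p(scaled.data)
    out = ad.AnnData(X=scaled, obs=adata.obs.copy(), var=adata.var.copy(), uns=dict(adata.uns))
    out.layers["counts"] = sp.csr_matrix(adata.X).copy()
    out.uns["normalization"] = {"scale_factor": scale_factor, "is_log1p": True}
    return out


def select_hvg(norm: ad.AnnData, n_hvg: int = 2000) -> np.ndarray:
    """Rank genes by standardized variance of raw counts (vst dialect).

    A quadratic mean–variance trend is fit on log10 scale, counts are
    standardized by the trend-expected standard deviation, clipped at
    ``sqrt(n_cells)``, and genes are ranked by the variance of the clipped
    values.  Ties break by gene order.  Returns gene integer indices.
    """
    counts = norm.layers.get("counts")
    if counts is None:
        counts = norm.X
    X = sp.csc_matrix(counts, dtype=float)
    n = X.shape[0]
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)

    std_var = np.zeros(X.shape[1])
    positive = (var > 0) & (mean > 0)
    if positive.any():
        logm, logv = np.log10(mean[positive]), np.log10(var[positive])
        coef = np.polyfit(logm, logv, deg=min(2, max(1, positive.sum() - 1)))
        exp_sd = np.sqrt(10 ** np.polyval(coef, np.log10(mean[positive])))
        clip = np.sqrt(n)
        idx = np.where(positive)[0]
        for j, g in enumerate(idx):
            col = X.getcol(g)
            z = np.minimum((col.data - mean[g]) / exp_sd[j], clip)
            z0 = np.minimum((0.0 - mean[g]) / exp_sd[j], clip)
            n_zero = n - col.nnz
            total = z.sum() + n_zero * z0
            total_sq = (z**2).sum() + n_zero * z0**2
            std_var[g] = (total_sq - total**2 / n) / max(n - 1, 1)
    order = np.argsort(-std_var, kind="stable")
    return order[: min(n_hvg, X.shape[1])]


def pca_embed(
    norm: ad.AnnData,
    hvg: np.ndarray | None = None,
    n_comps: int = 30,
    clip: float = 10.0,
    random_state: int = 0,
) -> tuple[np.ndarray, dict]:
    """Scaled, clipped PCA of the normalized matrix on the HVG subset.

    Genes are centered and scaled to unit variance, values clipped at
    ``+/- clip``, and the decomposition sign-fixed so each component's
    largest-magnitude loading is positive.  Returns (embedding, info).
    """
    X = norm.X
    if hvg is not None:
        X = X[:, np.asarray(hvg)]
    dense = np.asarray(X.todense()) if sp.issparse(X) else np.array(X, dtype=float)
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    scaled = np.clip((dense - mu) / sd, -clip, clip)
    n_comps = min(n_comps, min(scaled.shape) - 1)
    pca = PCA(n_components=n_comps, svd_solver="randomized", random_state=random_state)
    emb = pca.fit_transform(scaled)
    comps = pca.components_
    flip = np.sign(comps[np.arange(n_comps), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    emb = emb * flip[None, :]
    info = {
        "components": comps * flip[:, None],
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "mean": mu,
        "scale": sd,
    }
    return emb, info


def _snn_graph(embedding: np.ndarray, k_neighbors: int) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph (includes self in the
    neighbor sets, like the conventional implementation)."""
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    knn = nn.kneighbors_graph(embedding, mode="connectivity")
    knn = knn.tolil()
    knn.setdiag(1)
    A = sp.csr_matrix(knn)
    shared = (A @ A.T).tocoo()
    k = np.asarray(A.sum(axis=1)).ravel()
    union = k[shared.row] + k[shared.col] - shared.data
    w = shared.data / union
    keep = (w >= SNN_PRUNE) & (shared.row != shared.col)
    snn = sp.csr_matrix((w[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    return snn.maximum(snn.T)


def cluster_graph(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterResult:
    """Partition the SNN graph by Leiden modularity at ``resolution``.

    Labels are renumbered by decreasing cluster size; a fixed ``seed`` makes
    the partition deterministic.
    """
    n = embedding.shape[0]
    if n <= k_neighbors:
        raise ValueError(f"need more than k_neighbors={k_neighbors} cells, got {n}")
    snn = _snn_graph(embedding, k_neighbors)
    coo = sp.triu(snn, k=1).tocoo()
    g = igraph.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=5,
    )
    raw = np.array(part.membership)
    order = pd.Series(raw).value_counts().index.to_numpy()
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(l)] for l in raw])
    return ClusterResult(
        labels=labels,
        resolution=resolution,
        n_clusters=len(order),
        embedding=embedding,
    )


def silhouette_by_cluster(embedding: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Mean Euclidean silhouette per cluster; size-1 clusters score 0.

    With a single cluster overall the silhouette is undefined and every
    cluster scores 0 (with a warning).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        warnings.warn("silhouette undefined for a single cluster; returning 0")
        return {int(u): 0.0 for u in uniq}
    samples = silhouette_samples(embedding, labels)
    return {int(u): float(samples[labels == u].mean()) for u in uniq}
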