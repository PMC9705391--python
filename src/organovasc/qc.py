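"""Cell and gene quality control for UMI count matrices.

Cells are kept when they show at least 200 and at most 7500 unique genes and
at most 10% mitochondrial content; the wording of the underlying protocol is
strict ("fewer than", "more than"), so boundary values survive.  Genes must
be detected in at least 3 cells, evaluated *after* cell filtering (the
convention of creating the object from already cell-filtered data).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import QCError

__all__ = ["QCThresholds", "compute_qc_metrics", "qc_filter"]


@dataclass(frozen=True)
class QCThresholds:
    """Filtering thresholds; defaults are the study settings."""

    min_genes: int = 200
    max_genes: int = 7500
    max_pct_mito: float = 10.0
    min_cells_per_gene: int = 3

    def __post_init__(self):
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be smaller than max_genes")
        if min(self.min_genes, self.max_pct_mito, self.min_cells_per_gene) < 0:
            raise ValueError("thresholds must be non-negative")


def compute_qc_metrics(
    adata: ad.AnnData,
    mito_prefix: str = "MT-",
    ribo_prefixes: tuple[str, ...] = ("RPS", "RPL"),
) -> pd.DataFrame:
    """Per-cell QC metrics: unique genes, total counts, %mito, %ribo.

    Gene families are identified by symbol prefix (``mito_prefix`` may be a
    regular expression). Cells with zero total counts get percentage fields
    of 0 and are flagged in the ``zero_counts`` column.
    """
    X = sp.csr_matrix(adata.X)
    genes = adata.var_names.to_numpy(dtype=object)
    mito_mask = np.array([bool(re.match(mito_prefix, g)) for g in genes])
    ribo_mask = np.array([any(g.startswith(p) for p in ribo_prefixes) for g in genes])
    if not mito_mask.any():
        warnings.warn(f"no genes match mitochondrial prefix {mito_prefix!r}; pct_mito is 0")

    total = np.asarray(X.sum(axis=1)).ravel()
    n_unique = X.getnnz(axis=1)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros_like(total)
    ribo = np.asarray(X[:, ribo_mask].sum(axis=1)).ravel() if ribo_mask.any() else np.zeros_like(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(total > 0, 100.0 * mito / total, 0.0)
        pct_ribo = np.where(total > 0, 100.0 * ribo / total, 0.0)
    return pd.DataFrame(
        {
            "n_unique_genes": n_unique.astype(int),
            "total_counts": total.astype(int),
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
            "zero_counts": total == 0,
        },
        index=adata.obs_names,
    )


def qc_filter(
    adata: ad.AnnData,
    metrics: pd.DataFrame | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Filter cells then genes; return the kept matrix and a removal log.

    A cell is kept iff ``min_genes <= n_unique_genes <= max_genes`` and
    ``pct_mito <= max_pct_mito`` (strict violations are removed; boundary
    values stay). A gene is kept iff it has a nonzero count in at least
    ``min_cells_per_gene`` cells of the *cell-filtered* matrix.  The log has
    one row per (entity, id, rule) triple.
    """
    if metrics is None:
        metrics = compute_qc_metrics(adata)
    metrics = metrics.loc[adata.obs_names]
    t = thresholds
    too_few = metrics["n_unique_genes"] < t.min_genes
    too_many = metrics["n_unique_genes"] > t.max_genes
    too_mito = metrics["pct_mito"] > t.max_pct_mito

    log_rows = []
    for rule, mask in (
        ("min_genes", too_few),
        ("max_genes", too_many),
        ("max_pct_mito", too_mito),
    ):
        for bc in metrics.index[mask]:
            log_rows.append(("cell", bc, rule))

    keep_cells = ~(too_few | too_many | too_mito)
    if not keep_cells.any():
        raise QCError("quality control removed every cell")
    filtered = adata[keep_cells.to_numpy()].copy()

    detected = sp.csr_matrix(filtered.X).getnnz(axis=0)
    keep_genes = detected >= t.min_cells_per_gene
    for g in filtered.var_names[~keep_genes]:
        log_rows.append(("gene", g, "min_cells_per_gene"))
    filtered = filtered[:, keep_genes].copy()

    log = pd.DataFrame(log_rows, columns=["entity", "id", "rule"])
    return filtered, log
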