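"""Reading and writing of the 10x-style MTX triplet and cell metadata.

The on-disk layout mirrors CellRanger's filtered output: ``matrix.mtx``
(genes x cells, MatrixMarket integer), ``features.tsv`` (one gene symbol per
line) and ``barcodes.tsv``.  Cell metadata (condition labels, ground-truth
classes) travels in a separate ``cell_metadata.csv`` keyed by barcode.
"""

from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["write_10x_mtx", "read_10x_mtx", "write_cell_metadata", "read_cell_metadata"]


def write_10x_mtx(adata: ad.AnnData, outdir: str | os.PathLike) -> Path:
    """Write ``adata`` (cells x genes) as a genes-x-cells MTX triplet.

    Also writes ``cell_metadata.csv`` if ``adata.obs`` carries any columns.
    Returns the output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.csc_matrix(adata.X.T)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    if adata.obs.shape[1]:
        write_cell_metadata(adata.obs, outdir)
    return outdir


def read_10x_mtx(indir: str | os.PathLike) -> ad.AnnData:
    """Read an MTX triplet back into a cells-x-genes :class:`AnnData`."""
    indir = Path(indir)
    mat = scipy.io.mmread(str(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    x = sp.csr_matrix(mat.T)
    adata = ad.AnnData(
        X=x,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    meta = indir / "cell_metadata.csv"
    if meta.exists():
        obs = read_cell_metadata(indir).reindex(adata.obs_names)
        for col in obs.columns:
            adata.obs[col] = obs[col]
    return adata


def write_cell_metadata(obs: pd.DataFrame, outdir: str | os.PathLike) -> Path:
    path = Path(outdir) / "cell_metadata.csv"
    obs.rename_axis("barcode").to_csv(path)
    return path


def read_cell_metadata(indir: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(Path(indir) / "cell_metadata.csv", index_col="barcode")
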