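"""Reading and writing CellRanger-style MTX triplets around AnnData.

The universal in-memory container of the package is an
:class:`anndata.AnnData` with

* ``X`` — sparse CSR cell x gene UMI counts,
* ``obs`` — per-cell metadata with at least ``sample`` and ``batch``,
* ``var`` — per-gene table with ``gene_symbol`` and boolean flags
  ``is_mito``, ``is_ribo``, ``is_hb``.

On disk each sample is a plain-text triplet (``matrix.mtx`` with genes as
rows, ``barcodes.tsv``, ``features.tsv``), plus a ``cells.csv`` with the
cell metadata.
"""
from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

GENE_FLAG_COLUMNS = ("is_mito", "is_ribo", "is_hb")


def write_sample_mtx(adata: ad.AnnData, outdir: str | os.PathLike) -> None:
    """Write one sample's counts as an uncompressed MTX triplet (genes x cells)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.csc_matrix(adata.X).T  # genes as rows, CellRanger convention
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.astype(int))
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv",
                                      sep="\t", index=False, header=False)
    feat = pd.DataFrame({
        "gene_id": adata.var_names,
        "gene_symbol": adata.var.get("gene_symbol", adata.var_names),
    })
    for col in GENE_FLAG_COLUMNS:
        feat[col] = adata.var[col].astype(int).to_numpy() if col in adata.var \
            else 0
    feat.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)


def read_sample_mtx(indir: str | os.PathLike) -> ad.AnnData:
    """Read one triplet written by :func:`write_sample_mtx`."""
    indir = Path(indir)
    X = scipy.io.mmread(str(indir / "matrix.mtx"))
    X = sp.csr_matrix(X.T)  # back to cells x genes
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0] \
        if (indir / "barcodes.tsv").stat().st_size else pd.Series([], dtype=str)
    feat = pd.read_csv(indir / "features.tsv", sep="\t", header=None,
                       names=["gene_id", "gene_symbol", *GENE_FLAG_COLUMNS])
    var = feat.set_index("gene_id")
    var.index.name = None
    for col in GENE_FLAG_COLUMNS:
        var[col] = var[col].astype(bool)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes.astype(str), name=None)),
        var=var,
    )
    return adata


def write_experiment(adata: ad.AnnData, outdir: str | os.PathLike,
                     overwrite: bool = False) -> None:
    """Write a multi-sample experiment: one MTX triplet per sample + cells.csv."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise IOError(f"{outdir} exists and is not empty; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)
    samples = adata.obs["sample"].astype(str)
    for sample in pd.unique(samples):
        write_sample_mtx(adata[samples == sample], outdir / f"sample_{sample}")
    cells = adata.obs.reset_index(names="barcode")
    cells.to_csv(outdir / "cells.csv", index=False)


def read_experiment(indir: str | os.PathLike) -> ad.AnnData:
    """Read an experiment written by :func:`write_experiment`."""
    indir = Path(indir)
    cells = pd.read_csv(indir / "cells.csv", dtype={"barcode": str})
    parts = []
    for sample in pd.unique(cells["sample"].astype(str)):
        parts.append(read_sample_mtx(indir / f"sample_{sample}"))
    adata = ad.concat(parts, join="outer", merge="first") if len(parts) > 1 \
        else parts[0]
    adata = adata[cells["barcode"].to_numpy()].copy()
    adata.obs = cells.set_index("barcode")
    adata.obs.index.name = None
    return adata
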