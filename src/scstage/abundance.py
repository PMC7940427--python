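"""Differential abundance of cell types along the scaled progression axis.

Cluster cell counts per sample are converted to normalised log counts
(CPM-style with a library-size-adjusted prior), each eligible cluster's
abundance is regressed on the 0-1 scaled PC1 values with Huber robust
regression, significance comes from a robust Wald (slope) test, and
p-values are BH-adjusted across the tested clusters. Because the predictor
spans [0, 1], the slope (logFC) reads as the estimated change in normalised
log abundance from the first to the last sample. Only clusters averaging
more than ``min_mean_cells`` cells per sample are tested.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .statcore import bh_adjust, huber_fit, robust_slope_test

__all__ = ["abundance_matrix", "differential_abundance"]


def abundance_matrix(labels, samples, prior_count: float = 2.0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalised log cluster abundances (clusters x samples).

    For cluster c in sample s with x of N cells:
    ``log2((x + p_s) / (N + 2 p_s) * 1e6)`` with the library-size-adjusted
    prior ``p_s = prior_count * N_s / mean(N)``.

    Returns ``(log_cpm, raw_counts)`` with identical shapes.
    """
    labels = pd.Series(np.asarray(labels).astype(str))
    samples = pd.Series(np.asarray(samples).astype(str))
    tab = pd.crosstab(labels, samples)
    totals = tab.sum(axis=0).to_numpy(dtype=float)
    if np.any(totals == 0):
        tab = tab.loc[:, tab.sum(axis=0) > 0]
        totals = tab.sum(axis=0).to_numpy(dtype=float)
    prior = prior_count * totals / totals.mean()
    x = tab.to_numpy(dtype=float)
    log_cpm = np.log2((x + prior[None, :]) / (totals + 2 * prior)[None, :]
                      * 1e6)
    return pd.DataFrame(log_cpm, index=tab.index, columns=tab.columns), tab


def differential_abundance(abund: pd.DataFrame, pc1_scaled: pd.Series,
                           counts: pd.DataFrame | None = None,
                           samples_in_scope=None,
                           min_mean_cells: float = 10.0,
                           max_it: int = 100) -> pd.DataFrame:
    """Robust-regression differential abundance per cluster.

    ``abund`` is the clusters x samples normalised log abundance matrix;
    ``pc1_scaled`` the per-sample 0-1 scaled PC1 values. ``counts`` (raw
    cluster cell counts) drives the eligibility filter: a cluster is tested
    only when its mean cells per in-scope sample exceeds
    ``min_mean_cells``. ``samples_in_scope`` restricts the fit (e.g. to
    stages 1-4, excluding tumour samples).
    """
    if samples_in_scope is None:
        samples_in_scope = [s for s in abund.columns if s in pc1_scaled.index]
    samples_in_scope = [s for s in samples_in_scope if s in abund.columns]
    if len(samples_in_scope) < 6:
        raise ValueError("need at least 6 samples in scope")
    x = pc1_scaled.loc[samples_in_scope].to_numpy(dtype=float)
    rows = []
    for clust in abund.index:
        y = abund.loc[clust, samples_in_scope].to_numpy(dtype=float)
        if counts is not None:
            mean_cells = float(
                counts.loc[clust, samples_in_scope].mean())
        else:
            mean_cells = np.inf
        tested = mean_cells > min_mean_cells
        if not tested:
            rows.append((clust, np.nan, np.nan, mean_cells, False))
            continue
        if np.ptp(y) == 0:
            rows.append((clust, 0.0, 1.0, mean_cells, True))
            continue
        fit = huber_fit(x, y, max_it=max_it)
        p = robust_slope_test(fit)
        rows.append((clust, fit.slope, p, mean_cells, True))
    res = pd.DataFrame(rows, columns=["cluster", "logFC", "p",
                                      "mean_cells_per_sample", "tested"]) \
        .set_index("cluster")
    res["fdr"] = np.nan
    tested_mask = res["tested"].to_numpy()
    if tested_mask.any():
        res.loc[tested_mask, "fdr"] = bh_adjust(
            res.loc[tested_mask, "p"].to_numpy())
    return res
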