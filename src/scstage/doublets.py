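"""Doublet scoring and cluster-level artifact removal.

Per-cell doublet scores compare the local density of simulated doublets
(sums of random cell pairs) to the local density of observed cells in HVG
PCA space. Flagging then happens at cluster level in two rounds: highly
resolved per-sample clusters with an outlying median score that are small
(< 5% of the sample) are tagged first; coarse clusters with an outlying
proportion of round-1 cells are tagged second. Contaminant clusters are
removed by two expression rules: non-zero median haemoglobin expression
(red blood cells) and median mitochondrial fraction below 0.005 (stripped
nuclei).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .statcore import scaled_mad
from . import cluster as _cluster

__all__ = [
    "doublet_scores",
    "doublet_cluster_rounds",
    "flag_contaminant_clusters",
    "detect_artifacts",
]


def doublet_scores(counts, hvg_mask, n_synthetic: int = 2000, k: int = 50,
                   d: int = 25, seed: int = 0) -> np.ndarray:
    """Density-ratio doublet score for the cells of one sample.

    ``counts`` is the raw cell x gene matrix of a single sample; synthetic
    doublets are sums of random cell pairs. All profiles are library-size
    normalised, log-transformed and embedded by PCA on the HVGs; the score
    is the kernel density of synthetic doublets around each cell divided by
    the kernel density of observed cells, with a Gaussian bandwidth set to
    the median distance to the k-th cell neighbour.
    """
    X = sp.csr_matrix(counts)
    n = X.shape[0]
    if n < 100:
        warnings.warn("fewer than 100 cells; doublet scores are unstable")
    if n_synthetic < 10 * k:
        warnings.warn("n_synthetic < 10*k; density estimates may be coarse")
    rng = np.random.default_rng(seed)
    a = rng.integers(0, n, n_synthetic)
    b = rng.integers(0, n, n_synthetic)
    D = X[a] + X[b]

    def embed(M):
        lib = np.asarray(M.sum(axis=1)).ravel()
        lib = np.maximum(lib, 1.0)
        Mn = sp.diags(np.median(lib) / lib) @ M
        return np.log1p(Mn[:, hvg_mask].toarray())

    cells = embed(X)
    doubs = embed(D)
    mean = cells.mean(axis=0)
    d_eff = min(d, *cells.shape)
    _, _, Vt = np.linalg.svd(cells - mean, full_matrices=False)
    Vt = Vt[:d_eff]
    pc_cells = (cells - mean) @ Vt.T
    pc_doubs = (doubs - mean) @ Vt.T

    from sklearn.neighbors import NearestNeighbors
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pc_cells)
    dist_self, _ = nn.kneighbors(pc_cells)
    h = max(float(np.median(dist_self[:, -1])), 1e-9)

    # kernel sums via chunked pairwise distances
    def density(query, ref):
        out = np.zeros(query.shape[0])
        step = 512
        for i in range(0, query.shape[0], step):
            q = query[i:i + step]
            d2 = ((q[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
            out[i:i + step] = np.exp(-0.5 * d2 / h ** 2).sum(axis=1)
        return out

    dens_doub = density(pc_cells, pc_doubs) / max(n_synthetic, 1)
    dens_cell = density(pc_cells, pc_cells) / n
    return dens_doub / np.maximum(dens_cell, 1e-300)


def doublet_cluster_rounds(scores, fine_clusters, coarse_clusters,
                           samples=None, score_k: float = 1.5,
                           max_frac: float = 0.05,
                           prop_k: float = 2.0,
                           min_round2_frac: float = 0.1) -> pd.DataFrame:
    """Two-round cluster-level doublet flagging.

    Round 1 (within each sample): fine clusters whose median score exceeds
    ``median + score_k * MAD`` of the cluster-median scores *and* that hold
    less than ``max_frac`` of the sample's cells are flagged entirely.
    Round 2 (dataset-wide): coarse clusters whose fraction of round-1 cells
    exceeds ``median + prop_k * MAD`` of the cluster fractions are flagged.
    Because most clusters typically contain no round-1 cells (making the
    MAD zero), round 2 additionally requires the fraction to reach
    ``min_round2_frac`` — a cluster that is overwhelmingly unflagged cells
    is not a doublet cluster.
    """
    scores = np.asarray(scores, float)
    fine = np.asarray(fine_clusters)
    coarse = np.asarray(coarse_clusters)
    n = scores.size
    samples = np.zeros(n, dtype=int) if samples is None else np.asarray(samples)

    round1 = np.zeros(n, dtype=bool)
    for s in pd.unique(samples):
        sidx = np.where(samples == s)[0]
        labs = fine[sidx]
        uniq = pd.unique(labs)
        if uniq.size < 2:
            warnings.warn(f"sample {s!r}: single fine cluster, round-1 rule "
                          "degenerate")
            continue
        med = np.array([np.median(scores[sidx][labs == c]) for c in uniq])
        sizes = np.array([(labs == c).sum() for c in uniq])
        cut = np.median(med) + score_k * scaled_mad(med)
        flag = (med > cut) & (sizes < max_frac * sidx.size)
        for c, f in zip(uniq, flag):
            if f:
                round1[sidx[labs == c]] = True

    uniq_c = pd.unique(coarse)
    round2 = np.zeros(n, dtype=bool)
    if uniq_c.size >= 2:
        fracs = np.array([round1[coarse == c].mean() for c in uniq_c])
        cut2 = np.median(fracs) + prop_k * scaled_mad(fracs)
        for c, fr in zip(uniq_c, fracs):
            if fr > cut2 and fr >= min_round2_frac:
                round2[coarse == c] = True
    else:
        warnings.warn("single coarse cluster, round-2 rule degenerate")

    return pd.DataFrame({
        "doublet_score": scores,
        "round1_doublet": round1,
        "round2_doublet": round2,
    })


def flag_contaminant_clusters(logexpr, clusters, hb_mask,
                              pct_mito) -> pd.DataFrame:
    """Flag RBC and stripped-nuclei clusters.

    A cluster is RBC-like when the median (over its cells) of summed
    haemoglobin log-expression exceeds 0, and stripped-nuclei-like when the
    median mitochondrial fraction falls below 0.005.
    """
    hb_mask = np.asarray(hb_mask, bool)
    if hb_mask.sum() == 0:
        raise ValueError("haemoglobin gene set is empty")
    X = sp.csr_matrix(logexpr)
    hb_sum = np.asarray(X[:, hb_mask].sum(axis=1)).ravel()
    pct_mito = np.asarray(pct_mito, float)
    clusters = np.asarray(clusters)
    rbc = np.zeros(clusters.size, dtype=bool)
    nuc = np.zeros(clusters.size, dtype=bool)
    for c in pd.unique(clusters):
        m = clusters == c
        if np.median(hb_sum[m]) > 0:
            rbc[m] = True
        if np.median(pct_mito[m]) < 0.005:
            nuc[m] = True
    return pd.DataFrame({"rbc": rbc, "stripped_nucleus": nuc})


def detect_artifacts(adata, logexpr, hvg_mask, pct_mito,
                     n_synthetic: int = 1500, k_score: int = 50,
                     fine_k: int = 8, fine_steps: int = 3,
                     coarse_k: int = 15, coarse_steps: int = 7,
                     seed: int = 0) -> pd.DataFrame:
    """End-to-end artifact detection for a multi-sample experiment.

    Scores doublets per sample, forms highly resolved per-sample clusters
    and dataset-wide coarse clusters (SNN + walktrap), applies the
    two-round doublet rule and the contaminant-cluster rules, and assigns a
    single ``removal_reason`` per cell (doublet before rbc before nucleus).
    """
    samples = adata.obs["sample"].to_numpy()
    X = sp.csr_matrix(adata.X)
    L = sp.csr_matrix(logexpr)
    n = adata.n_obs
    scores = np.zeros(n)
    fine = np.empty(n, dtype=object)
    for s in pd.unique(samples):
        idx = np.where(samples == s)[0]
        scores[idx] = doublet_scores(X[idx], hvg_mask,
                                     n_synthetic=n_synthetic,
                                     k=min(k_score, idx.size - 1), seed=seed)
        emb = _cluster.pca_embed(L[idx][:, hvg_mask],
                                 d=min(25, idx.size - 1, int(hvg_mask.sum())))
        g = _cluster.snn_graph(emb.coords, k=min(fine_k, idx.size - 1))
        labs = _cluster.community_cluster(g, steps=fine_steps).labels
        fine[idx] = [f"{s}:{c}" for c in labs]

    emb_all = _cluster.pca_embed(L[:, hvg_mask],
                                 d=min(25, n - 1, int(hvg_mask.sum())))
    g_all = _cluster.snn_graph(emb_all.coords, k=min(coarse_k, n - 1))
    coarse = _cluster.community_cluster(g_all, steps=coarse_steps) \
        .labels.to_numpy()

    flags = doublet_cluster_rounds(scores, fine, coarse, samples=samples)
    contam = flag_contaminant_clusters(
        L, coarse, adata.var["is_hb"].to_numpy(), pct_mito)
    flags = pd.concat([flags.reset_index(drop=True),
                       contam.reset_index(drop=True)], axis=1)
    flags.index = adata.obs_names

    reason = np.array([""] * n, dtype=object)
    doublet = flags["round1_doublet"] | flags["round2_doublet"]
    reason[doublet.to_numpy()] = "doublet"
    reason[(reason == "") & flags["rbc"].to_numpy()] = "rbc"
    reason[(reason == "") & flags["stripped_nucleus"].to_numpy()] = "nucleus"
    flags["removal_reason"] = reason
    flags["coarse_cluster"] = coarse
    flags["fine_cluster"] = fine
    return flags
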