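"""Embedding, batch integration and graph-based clustering.

PCA on HVG log-expression (deterministic sign convention), a simplified
mutual-nearest-neighbour batch correction (sequential merge, per-pair
correction vectors smoothed with a Gaussian kernel), a shared-nearest-
neighbour graph with rank weights, random-walk (walktrap) community
detection, and iterative merging of clusters separated by fewer than a
minimum number of differentially expressed genes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .statcore import bh_adjust

__all__ = [
    "Embedding",
    "ClusterAssignment",
    "pca_embed",
    "mnn_correct",
    "snn_graph",
    "community_cluster",
    "merge_by_de",
    "subcluster",
]


@dataclass
class Embedding:
    coords: np.ndarray                  # cells x d
    provenance: str = "pca"             # "pca" | "mnn"
    batches: np.ndarray | None = None
    explained_variance: np.ndarray | None = None
    components: np.ndarray | None = None  # d x genes loadings
    mean: np.ndarray | None = None


@dataclass
class ClusterAssignment:
    labels: pd.Series                   # per cell, string labels
    stage: str = "initial"              # initial | merged | final
    params: dict = field(default_factory=dict)
    merge_history: list = field(default_factory=list)  # (from, to) events


def pca_embed(logexpr, d: int = 50, batches=None) -> Embedding:
    """Centered PCA with a deterministic sign convention.

    Each component is flipped so that its largest-magnitude loading is
    positive, making the embedding reproducible across runs.
    """
    X = logexpr.toarray() if sp.issparse(logexpr) else np.asarray(logexpr, float)
    n, g = X.shape
    if d > min(n, g):
        raise ValueError(f"d={d} exceeds min(n_cells, n_genes)={min(n, g)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :d], S[:d], Vt[:d]
    signs = np.sign(Vt[np.arange(d), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    coords = Xc @ Vt.T
    return Embedding(coords=coords, provenance="pca",
                     batches=None if batches is None else np.asarray(batches),
                     explained_variance=S ** 2 / max(n - 1, 1),
                     components=Vt, mean=mean)


def mnn_correct(embedding: Embedding, k: int = 20) -> Embedding:
    """Mutual-nearest-neighbour correction of batch shifts in PCA space.

    Batches are merged sequentially, largest first. For each incoming batch,
    MNN pairs against the accumulated reference define per-pair correction
    vectors (reference minus incoming). A paired incoming cell moves by the
    mean of its own pair vectors (exact-distance-zero matches take
    precedence, so duplicated batches are left untouched); unpaired cells
    receive a Gaussian-kernel weighted average of the paired cells'
    corrections. The reference batch is never moved. As with any
    mutual-neighbour matching, shifts are recovered faithfully when they
    are roughly orthogonal to the biological structure.
    """
    if embedding.batches is None:
        raise ValueError("embedding has no batch information")
    coords = embedding.coords.copy()
    batches = np.asarray(embedding.batches)
    uniq, counts = np.unique(batches, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 batches")
    order = uniq[np.argsort(-counts)]
    for b in order:
        if np.sum(batches == b) < k:
            raise ValueError(f"batch {b!r} has fewer than k={k} cells")

    ref_idx = np.where(batches == order[0])[0]
    for b in order[1:]:
        new_idx = np.where(batches == b)[0]
        R, N = coords[ref_idx], coords[new_idx]
        k_eff = min(k, len(R), len(N))
        nn_rn = NearestNeighbors(n_neighbors=k_eff).fit(N)
        _, r_to_n = nn_rn.kneighbors(R)          # neighbours of ref in new
        nn_nr = NearestNeighbors(n_neighbors=k_eff).fit(R)
        _, n_to_r = nn_nr.kneighbors(N)          # neighbours of new in ref
        r_sets = [set(row) for row in r_to_n]
        corr = np.zeros_like(N)
        paired = np.zeros(len(N), dtype=bool)
        for ni in range(len(N)):
            partners = [ri for ri in n_to_r[ni] if ni in r_sets[ri]]
            if not partners:
                continue
            vecs = R[partners] - N[ni]
            d = np.linalg.norm(vecs, axis=1)
            exact = d < 1e-12 * max(1.0, np.abs(N).max())
            corr[ni] = vecs[exact].mean(axis=0) if exact.any() \
                else vecs.mean(axis=0)
            paired[ni] = True
        if not paired.any():
            raise ValueError("batches share no neighbourhood: no MNN pairs")
        if not paired.all():
            anchor_pts = N[paired]
            nn_anchor = NearestNeighbors(
                n_neighbors=min(int(paired.sum()), k_eff)).fit(anchor_pts)
            dist, aidx = nn_anchor.kneighbors(N[~paired])
            sigma = max(float(np.median(dist[:, 0])), 1e-12)
            wts = np.exp(-0.5 * (dist / sigma) ** 2)
            wts = wts / wts.sum(axis=1, keepdims=True)
            corr[~paired] = np.einsum("nk,nkd->nd", wts,
                                      corr[paired][aidx])
        coords[new_idx] = N + corr
        ref_idx = np.concatenate([ref_idx, new_idx])
    return Embedding(coords=coords, provenance="mnn", batches=batches,
                     explained_variance=embedding.explained_variance,
                     components=embedding.components, mean=embedding.mean)


def snn_graph(coords: np.ndarray, k: int = 20) -> igraph.Graph:
    """Shared-nearest-neighbour graph with rank weights.

    Cells i and j are connected when their k-NN sets (each including the
    cell itself) intersect; the edge weight is ``k - r/2`` where r is the
    smallest sum of neighbour ranks over shared neighbours (the cell itself
    has rank 0). Self-loops are excluded.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    _, idx = nn.kneighbors(coords)  # includes self at rank 0 (distance 0)

    # for every shared neighbour v, all (i, j) with v in both kNN sets
    # contribute a rank sum; the edge keeps the smallest sum
    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    ranks = np.tile(np.arange(k), n).astype(np.int64)
    order = np.argsort(cols, kind="mergesort")
    cols_s, rows_s, ranks_s = cols[order], rows[order], ranks[order]
    starts = np.searchsorted(cols_s, np.arange(n + 1))
    keys_all, sums_all = [], []
    for v in range(n):
        a, b = starts[v], starts[v + 1]
        if b - a < 2:
            continue
        members = rows_s[a:b]
        mranks = ranks_s[a:b]
        ii = members[:, None]
        jj = members[None, :]
        ss = mranks[:, None] + mranks[None, :]
        upper = ii < jj
        keys_all.append((ii * n + jj)[upper])
        sums_all.append(ss[upper])
    if not keys_all:
        return igraph.Graph(n=n)
    keys = np.concatenate(keys_all)
    sums = np.concatenate(sums_all)
    uniq_keys, inv = np.unique(keys, return_inverse=True)
    best = np.full(uniq_keys.size, np.iinfo(np.int64).max)
    np.minimum.at(best, inv, sums)
    w = k - best / 2.0
    keep = w > 0
    ei = (uniq_keys[keep] // n).astype(int)
    ej = (uniq_keys[keep] % n).astype(int)
    g = igraph.Graph(n=n, edges=list(zip(ei, ej)),
                     edge_attrs={"weight": w[keep].tolist()})
    return g


def community_cluster(graph: igraph.Graph, steps: int = 7,
                      stage: str = "initial") -> ClusterAssignment:
    """Walktrap community detection, cut at the modularity optimum."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    dendro = graph.community_walktrap(weights=weights, steps=steps)
    clustering = dendro.as_clustering()
    labels = pd.Series([f"c{m}" for m in clustering.membership])
    return ClusterAssignment(labels=labels, stage=stage,
                             params={"method": "walktrap", "steps": steps})


def _welch_de_count(X, idx_a, idx_b, min_lfc, fdr_cut, exclude=None):
    """Number of genes DE between two cell groups (Welch t + BH + LFC gate)."""
    Xa, Xb = X[idx_a], X[idx_b]
    ma = np.asarray(Xa.mean(axis=0)).ravel()
    mb = np.asarray(Xb.mean(axis=0)).ravel()
    va = np.asarray(Xa.power(2).mean(axis=0)).ravel() - ma ** 2
    vb = np.asarray(Xb.power(2).mean(axis=0)).ravel() - mb ** 2
    na, nb = len(idx_a), len(idx_b)
    va = va * na / max(na - 1, 1)
    vb = vb * nb / max(nb - 1, 1)
    se2 = va / na + vb / nb
    lfc = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(se2)
        df = se2 ** 2 / (va ** 2 / (na ** 2 * max(na - 1, 1))
                         + vb ** 2 / (nb ** 2 * max(nb - 1, 1)))
    valid = np.isfinite(t) & (se2 > 0)
    if exclude is not None:
        valid &= ~exclude
    p = np.ones(X.shape[1])
    p[valid] = 2 * stats.t.sf(np.abs(t[valid]), df[valid])
    q = np.ones_like(p)
    if valid.any():
        q[valid] = bh_adjust(p[valid])
    return int(np.sum((q < fdr_cut) & (np.abs(lfc) >= min_lfc) & valid))


def merge_by_de(logexpr, assignment: ClusterAssignment, min_de: int = 10,
                fdr: float = 0.1, min_lfc: float = 1.0,
                protected_pairs: set | None = None,
                exclude_genes=None) -> ClusterAssignment:
    """Iteratively merge cluster pairs separated by fewer than ``min_de`` genes.

    DE genes per pair: Welch t-test per gene on log-expression, BH within
    the pair, significant at ``q < fdr`` and ``|logFC| >= min_lfc``.
    The pair with the fewest DE genes merges first (ties: smaller combined
    size, then lexicographic). ``protected_pairs`` (frozensets of two
    labels) are never merged.
    """
    X = sp.csr_matrix(logexpr)
    protected = {frozenset(p) for p in (protected_pairs or set())}
    labels = assignment.labels.astype(str).copy()
    exclude = None if exclude_genes is None else np.asarray(exclude_genes, bool)
    history = list(assignment.merge_history)

    while True:
        uniq = sorted(labels.unique())
        if len(uniq) < 2:
            break
        members = {c: np.where(labels.to_numpy() == c)[0] for c in uniq}
        best = None
        for ai in range(len(uniq)):
            for bi in range(ai + 1, len(uniq)):
                a, b = uniq[ai], uniq[bi]
                if frozenset((a, b)) in protected:
                    continue
                nde = _welch_de_count(X, members[a], members[b],
                                      min_lfc, fdr, exclude)
                key = (nde, len(members[a]) + len(members[b]), a, b)
                if best is None or key < best:
                    best = key
        if best is None or best[0] >= min_de:
            break
        _, _, a, b = best
        labels[labels == b] = a
        history.append((b, a))

    return ClusterAssignment(labels=labels, stage="merged",
                             params={**assignment.params, "min_de": min_de,
                                     "fdr": fdr, "min_lfc": min_lfc},
                             merge_history=history)


def subcluster(coords: np.ndarray, labels: pd.Series, cluster_id: str,
               k: int = 20, steps: int = 4) -> pd.Series:
    """Re-cluster one cluster's cells on their own SNN graph.

    Returns a copy of ``labels`` where the target cluster's cells carry
    refined labels ``<cluster_id>.<i>``.
    """
    labels = labels.astype(str).copy()
    idx = np.where(labels.to_numpy() == cluster_id)[0]
    if idx.size <= k:
        return labels
    g = snn_graph(coords[idx], k=k)
    sub = community_cluster(g, steps=steps)
    new = [f"{cluster_id}.{m[1:]}" for m in sub.labels]
    labels.iloc[idx] = new
    return labels
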