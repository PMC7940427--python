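"""Ligand-receptor interaction scoring with a cluster-label permutation test.

For each (pair, sender type, receiver type) combination the score is the
mean of the ligand's average log-expression in the sender cluster and the
receptor's average in the receiver cluster. An expression gate requires
the ligand (receptor) to be detected in more than ``min_expr_frac`` of the
sender (receiver) cells. The null distribution shuffles cluster labels
across cells; p is the add-one fraction of permuted scores at least as
large as the observed one, BH-adjusted across all gated tests.
Stage-to-stage summaries count significant interactions per directed type
pair and report the net difference.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .statcore import bh_adjust

__all__ = [
    "read_lr_pairs",
    "score_interactions",
    "stage_interaction_delta",
    "group_labels",
]


def read_lr_pairs(path) -> pd.DataFrame:
    """Read a ligand-receptor pair table (TSV: pair_id, ligand, receptor)."""
    tab = pd.read_csv(path, sep="\t")
    required = {"pair_id", "ligand", "receptor"}
    if not required.issubset(tab.columns):
        raise ValueError(f"pair table must have columns {sorted(required)}")
    return tab


def group_labels(labels, mapping: dict) -> np.ndarray:
    """Map fine cluster labels onto coarser type names (e.g. Bsl* -> Basal)."""
    labels = np.asarray(labels).astype(object)
    return np.array([mapping.get(l, l) for l in labels], dtype=object)


def _cluster_stats(X, labels, uniq):
    """Per-cluster mean expression and detection fraction (genes x clusters)."""
    means, fracs = [], []
    for c in uniq:
        sub = X[np.asarray(labels) == c]
        means.append(np.asarray(sub.mean(axis=0)).ravel())
        fracs.append(np.asarray((sub > 0).mean(axis=0)).ravel())
    return np.column_stack(means), np.column_stack(fracs)


def score_interactions(adata, labels, pairs: pd.DataFrame,
                       n_perm: int = 1000, min_expr_frac: float = 0.1,
                       layer: str | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Permutation test of ligand-receptor signalling between cluster pairs.

    ``adata`` is an AnnData whose ``X`` (or ``layer``) holds log-normalised
    expression. Returns one row per (pair, sender, receiver) with the mean
    score, gating status, permutation p-value and BH FDR across gated
    tests. Pairs whose genes are absent from the matrix are dropped
    (counted in ``result.attrs['n_dropped_pairs']``).
    """
    X = adata.layers[layer] if layer is not None else adata.X
    return score_interactions_named(X, adata.var_names, labels, pairs,
                                    n_perm=n_perm,
                                    min_expr_frac=min_expr_frac, seed=seed)


def score_interactions_named(logexpr, gene_names, labels, pairs,
                             n_perm: int = 1000, min_expr_frac: float = 0.1,
                             seed: int = 0) -> pd.DataFrame:
    """Like :func:`score_interactions` with an explicit gene name vector."""
    X = sp.csr_matrix(logexpr)
    labels = np.asarray(labels).astype(str)
    uniq = sorted(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 cluster labels")
    for c in uniq:
        if (labels == c).sum() < 10:
            raise ValueError(f"cluster {c!r} has fewer than 10 cells")
    return _score_interactions_arr(X, labels, uniq, pairs,
                                   pd.Index(gene_names), n_perm,
                                   min_expr_frac, seed)


def _score_interactions_arr(X, labels, uniq, pairs, gene_index,
                            n_perm, min_expr_frac, seed):
    keep_rows, dropped = [], 0
    for _, row in pairs.iterrows():
        if row["ligand"] in gene_index and row["receptor"] in gene_index:
            keep_rows.append(row)
        else:
            dropped += 1
    if not keep_rows:
        raise ValueError("no ligand-receptor pair resolvable against matrix")
    ptab = pd.DataFrame(keep_rows).reset_index(drop=True)
    genes = sorted({*ptab["ligand"], *ptab["receptor"]})
    gidx = np.array([gene_index.get_loc(g) for g in genes])
    gpos = {g: i for i, g in enumerate(genes)}
    Xg = X[:, gidx].toarray()

    k = len(uniq)
    lab_codes = pd.Categorical(labels, categories=uniq).codes
    onehot = sp.csr_matrix(
        (np.ones(labels.size), (lab_codes, np.arange(labels.size))),
        shape=(k, labels.size))
    sizes = np.asarray(onehot.sum(axis=1)).ravel()
    means = (onehot @ Xg) / sizes[:, None]              # clusters x genes
    fracs = (onehot @ (Xg > 0)) / sizes[:, None]

    rows = []
    for pi, prow in ptab.iterrows():
        li, ri = gpos[prow["ligand"]], gpos[prow["receptor"]]
        for si, s in enumerate(uniq):
            for ci, c in enumerate(uniq):
                gated = (fracs[si, li] > min_expr_frac) and \
                        (fracs[ci, ri] > min_expr_frac)
                score = 0.5 * (means[si, li] + means[ci, ri])
                rows.append((prow["pair_id"], prow["ligand"],
                             prow["receptor"], s, c, score, gated, si, ci,
                             li, ri))
    res = pd.DataFrame(rows, columns=[
        "pair_id", "ligand", "receptor", "sender", "receiver", "mean_score",
        "gated", "_si", "_ci", "_li", "_ri"])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(res))
    obs = res["mean_score"].to_numpy()
    si_arr = res["_si"].to_numpy()
    ci_arr = res["_ci"].to_numpy()
    li_arr = res["_li"].to_numpy()
    ri_arr = res["_ri"].to_numpy()
    for _ in range(n_perm):
        perm = rng.permutation(labels.size)
        pmeans = (onehot @ Xg[perm]) / sizes[:, None]
        pscore = 0.5 * (pmeans[si_arr, li_arr] + pmeans[ci_arr, ri_arr])
        exceed += pscore >= obs
    res["p"] = (1.0 + exceed) / (1.0 + n_perm)

    gated_mask = res["gated"].to_numpy()
    res["fdr"] = np.nan
    if gated_mask.any():
        res.loc[gated_mask, "fdr"] = bh_adjust(
            res.loc[gated_mask, "p"].to_numpy())
    res["significant"] = gated_mask & (res["fdr"] < 0.05)
    res = res.drop(columns=["_si", "_ci", "_li", "_ri"])
    res.attrs["n_dropped_pairs"] = dropped
    return res


def stage_interaction_delta(results_a: pd.DataFrame, results_b: pd.DataFrame,
                            fdr_cut: float = 0.05
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Net change in significant interaction counts between two stages.

    ``delta(sender, receiver) = #significant in B - #significant in A`` per
    directed type pair. Returns ``(matrix, edge_list)``; the edge list also
    flags type pairs absent from one of the stages.
    """
    types_a = set(results_a["sender"]) | set(results_a["receiver"])
    types_b = set(results_b["sender"]) | set(results_b["receiver"])
    if not (types_a & types_b):
        raise ValueError("stage results share no cell types")
    types = sorted(types_a | types_b)

    def counts(res):
        sig = res[res["significant"] & (res["fdr"] < fdr_cut)]
        return sig.groupby(["sender", "receiver"]).size()

    ca, cb = counts(results_a), counts(results_b)
    mat = pd.DataFrame(0, index=types, columns=types, dtype=int)
    edges = []
    for s in types:
        for r in types:
            a = int(ca.get((s, r), 0))
            b = int(cb.get((s, r), 0))
            mat.loc[s, r] = b - a
            present = (s in types_a and r in types_a,
                       s in types_b and r in types_b)
            edges.append((s, r, a, b, b - a, all(present)))
    edge_list = pd.DataFrame(edges, columns=[
        "sender", "receiver", "n_significant_a", "n_significant_b", "delta",
        "present_in_both"])
    return mat, edge_list
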