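"""Anchored differential correlation between two conditions.

For every eligible gene, the Spearman correlation with an anchor gene
(e.g. the milk-protein gene Csn2) is computed separately in two groups of
cells (two conditions); the statistic is the difference of the two
correlations. Significance comes from a label-permutation null (group
labels shuffled over the pooled cells, optionally stratified by sample),
with the add-one two-sided p-value convention and BH adjustment. Genes
qualify only with at least ``min_nonzero`` non-zero observations in both
groups; a hit satisfies ``fdr < 0.001`` and ``|delta rho| > 0.3``. Each
gene's distance to the median correlation per condition is reported for
the classic two-axis visualisation.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

__all__ = ["anchored_spearman", "differential_correlation"]


def _rank_corr_matrix(X: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Spearman correlation of each column of X with the anchor vector."""
    rX = rankdata(X, axis=0)
    ra = rankdata(anchor)
    ra = ra - ra.mean()
    denom_a = np.sqrt(ra @ ra)
    rXc = rX - rX.mean(axis=0)
    denom_g = np.sqrt((rXc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rXc.T @ ra) / (denom_g * denom_a)
    rho[denom_g == 0] = np.nan
    if denom_a == 0:
        rho[:] = np.nan
    return rho


def anchored_spearman(logexpr, gene_names, anchor_gene: str,
                      cell_mask=None) -> pd.Series:
    """Spearman correlation of every gene with the anchor over a cell subset."""
    gene_names = pd.Index(gene_names)
    if anchor_gene not in gene_names:
        raise ValueError(f"anchor gene {anchor_gene!r} not found")
    X = logexpr.toarray() if sp.issparse(logexpr) else np.asarray(logexpr)
    if cell_mask is not None:
        X = X[np.asarray(cell_mask)]
    anchor = X[:, gene_names.get_loc(anchor_gene)]
    if np.ptp(anchor) == 0:
        raise ValueError("anchor uninformative: constant in the subset")
    rho = _rank_corr_matrix(X, anchor)
    return pd.Series(rho, index=gene_names)


def differential_correlation(logexpr, gene_names, anchor_gene: str,
                             groups, n_perm: int = 1000,
                             min_nonzero: int = 10,
                             fdr_cut: float = 0.001, drho_cut: float = 0.3,
                             samples=None, stratify: bool = False,
                             exhaustive: bool = False,
                             seed: int = 0) -> pd.DataFrame:
    """Permutation test for genes whose anchor correlation differs by condition.

    ``groups`` assigns each cell to one of exactly two conditions. The
    observed statistic per gene is ``delta_rho = rho_a - rho_b`` (conditions
    in sorted order); the null shuffles the group labels across cells and
    the two-sided p-value is ``(1 + #{|perm| >= |obs|}) / (1 + n_perm)``.

    ``stratify`` restricts shuffling to within-sample swaps; it only makes
    sense for designs where both conditions occur inside each sample (with
    sample-level conditions it would leave the labels unchanged), hence the
    plain shuffle is the default.

    ``exhaustive`` enumerates every distinct assignment of the group sizes
    to cells instead of sampling; the p-value is then the exact fraction of
    assignments (the observed one included) with ``|delta| >= |obs|``.
    Only feasible for tiny instances.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100: p-value resolution is very coarse")
    X = logexpr.toarray() if sp.issparse(logexpr) else np.asarray(logexpr)
    gene_names = pd.Index(gene_names)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValueError("exactly two groups required")
    mask_a = groups == uniq[0]
    mask_b = groups == uniq[1]
    if not exhaustive and (mask_a.sum() < 30 or mask_b.sum() < 30):
        raise ValueError("both groups need at least 30 cells")
    if exhaustive and (mask_a.sum() < 3 or mask_b.sum() < 3):
        raise ValueError("groups too small even for exhaustive enumeration")

    a_idx = gene_names.get_loc(anchor_gene)
    nz_a = (X[mask_a] != 0).sum(axis=0)
    nz_b = (X[mask_b] != 0).sum(axis=0)
    eligible = (nz_a >= min_nonzero) & (nz_b >= min_nonzero)
    eligible[a_idx] = False
    test_idx = np.where(eligible)[0]
    if test_idx.size == 0:
        raise ValueError("no gene passes the non-zero observation filter")

    sub = X[:, np.concatenate([[a_idx], test_idx])]

    def deltas(assign_a: np.ndarray) -> np.ndarray:
        Xa, Xb = sub[assign_a], sub[~assign_a]
        rho_a = _rank_corr_matrix(Xa[:, 1:], Xa[:, 0])
        rho_b = _rank_corr_matrix(Xb[:, 1:], Xb[:, 0])
        return rho_a - rho_b, rho_a, rho_b

    obs_delta, rho_a, rho_b = deltas(mask_a)

    n = groups.size
    if exhaustive:
        from itertools import combinations
        exceed = np.zeros(test_idx.size)
        total = 0
        for combo in combinations(range(n), int(mask_a.sum())):
            perm_a = np.zeros(n, dtype=bool)
            perm_a[list(combo)] = True
            d, _, _ = deltas(perm_a)
            exceed += (np.abs(np.nan_to_num(d))
                       >= np.abs(np.nan_to_num(obs_delta)))
            total += 1
        p = exceed / total
    else:
        rng = np.random.default_rng(seed)
        if stratify and samples is not None:
            samples = np.asarray(samples)
            strata = [np.where(samples == s)[0] for s in pd.unique(samples)]
        else:
            strata = [np.arange(n)]
        exceed = np.zeros(test_idx.size)
        base = mask_a.copy()
        for _ in range(n_perm):
            perm_a = np.zeros(n, dtype=bool)
            for idx in strata:
                shuffled = rng.permutation(idx)
                perm_a[shuffled] = base[idx]
            d, _, _ = deltas(perm_a)
            exceed += (np.abs(np.nan_to_num(d))
                       >= np.abs(np.nan_to_num(obs_delta)))
        p = (1.0 + exceed) / (1.0 + n_perm)

    from .statcore import bh_adjust
    fdr = bh_adjust(p)
    med_a = np.nanmedian(rho_a)
    med_b = np.nanmedian(rho_b)
    res = pd.DataFrame({
        "rho_a": rho_a,
        "rho_b": rho_b,
        "delta_rho": obs_delta,
        "dist_a": rho_a - med_a,
        "dist_b": rho_b - med_b,
        "p": p,
        "fdr": fdr,
        "n_nonzero_a": nz_a[test_idx],
        "n_nonzero_b": nz_b[test_idx],
    }, index=gene_names[test_idx])
    res["hit"] = (res["fdr"] < fdr_cut) & (res["delta_rho"].abs() > drho_cut)
    res.attrs["group_a"] = str(uniq[0])
    res.attrs["group_b"] = str(uniq[1])
    return res
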