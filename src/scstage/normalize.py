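"""Size factors by pooling-deconvolution, log-normalization and HVG selection.

Size factors are estimated per batch with the pooling-deconvolution
approach: cells are arranged on a ring ordered by library size, overlapping
pools of several sizes are summed, each pool's median ratio to an average
pseudo-cell gives one linear equation in the member cells' factors, and the
resulting system is solved by least squares. Factors are centred to mean 1
per batch; a cross-batch rescaling (down-scaling to the lowest-coverage
batch) puts all batches on a common scale before ``log2(x/sf + 1)``.

HVGs come from a per-gene variance decomposition: a loess trend of variance
on mean is the technical component; genes with positive residual
(biological) variance are highly variable, after dropping ribosomal- and
mitochondrial-flagged genes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import lsqr
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "NormalizationModel",
    "pooled_size_factors",
    "log_normalize",
    "select_hvgs",
    "fit_normalization",
]

# the published deconvolution default: pools of 21..101 cells in steps of 5
DEFAULT_POOL_SIZES = tuple(range(21, 102, 5))


@dataclass
class NormalizationModel:
    size_factors: pd.Series          # per cell, mean 1 per batch
    batch_rescale: dict[str, float]  # >= 1, lowest-coverage batch == 1
    pseudocount: float = 1.0
    log_base: float = 2.0
    pool_sizes: tuple[int, ...] = DEFAULT_POOL_SIZES


def _ring_order(libsize: np.ndarray) -> np.ndarray:
    """Order cells on a ring: ascending library size up, descending down.

    Adjacent ring positions then have similar library sizes all the way
    around, which keeps pool compositions smooth.
    """
    o = np.argsort(libsize, kind="mergesort")
    return np.concatenate([o[::2], o[1::2][::-1]])


def _pool_factors(counts: np.ndarray, pool_sizes) -> np.ndarray:
    """Deconvolve per-cell factors from pooled median ratios (one batch)."""
    n = counts.shape[0]
    lib = counts.sum(axis=1)
    ref = counts.mean(axis=0)
    expressed = ref > 0
    ref_e = ref[expressed]
    ring = _ring_order(lib)
    ring_counts = counts[ring][:, expressed]
    # prefix sums with wrap-around via doubling
    doubled = np.vstack([ring_counts, ring_counts])
    prefix = np.vstack([np.zeros((1, ring_counts.shape[1])),
                        np.cumsum(doubled, axis=0)])

    rows_i, cols_j, rhs = [], [], []
    eq = 0
    for k in pool_sizes:
        if k > n:
            continue
        for start in range(n):
            pooled = prefix[start + k] - prefix[start]
            ratio = np.median(pooled / ref_e)
            members = ring[np.arange(start, start + k) % n]
            rows_i.extend([eq] * k)
            cols_j.extend(members.tolist())
            rhs.append(ratio)
            eq += 1
    # low-weight per-cell anchors (library size) keep the system full rank
    w = 0.1
    mean_lib = lib.mean()
    for j in range(n):
        rows_i.append(eq)
        cols_j.append(j)
        rhs.append(w * lib[j] / mean_lib)
        eq += 1
    data = np.ones(len(rows_i))
    data[-n:] = w
    A = sp.csr_matrix((data, (rows_i, cols_j)), shape=(eq, n))
    theta = lsqr(A, np.asarray(rhs), atol=1e-12, btol=1e-12,
                 iter_lim=20000)[0]
    if np.any(theta <= 0):
        pos = theta[theta > 0]
        fill = pos.min() if pos.size else 1.0
        warnings.warn("negative deconvolved size factors clipped")
        theta = np.where(theta > 0, theta, fill)
    return theta / theta.mean()


def pooled_size_factors(counts, batches=None,
                        pool_sizes=DEFAULT_POOL_SIZES) -> np.ndarray:
    """Pooling-deconvolution size factors, estimated within each batch.

    Falls back to library-size factors (with a warning) for batches smaller
    than the smallest pool. Returned factors have mean 1 within each batch.
    """
    X = counts.toarray() if sp.issparse(counts) else np.asarray(counts, float)
    n = X.shape[0]
    if batches is None:
        batches = np.zeros(n, dtype=int)
    batches = np.asarray(batches)
    sf = np.empty(n)
    for b in pd.unique(batches):
        idx = np.where(batches == b)[0]
        sizes = [k for k in pool_sizes if k <= idx.size]
        if not sizes:
            warnings.warn(
                f"batch {b!r} smaller than the smallest pool; "
                "using library-size factors")
            lib = X[idx].sum(axis=1)
            sf[idx] = lib / lib.mean()
        else:
            sf[idx] = _pool_factors(X[idx], sizes)
    return sf


def _batch_rescale(counts, size_factors, batches) -> dict[str, float]:
    """Coverage ratio of each batch to the lowest-coverage batch (>= 1)."""
    lib = np.asarray(counts.sum(axis=1)).ravel()
    cov = {}
    for b in pd.unique(np.asarray(batches)):
        idx = np.asarray(batches) == b
        cov[b] = float(np.mean(lib[idx] / size_factors[idx]))
    lowest = min(cov.values())
    return {b: c / lowest for b, c in cov.items()}


def fit_normalization(adata, pool_sizes=DEFAULT_POOL_SIZES
                      ) -> NormalizationModel:
    """Estimate per-cell factors per batch and the cross-batch rescaling."""
    batches = adata.obs["batch"].to_numpy() if "batch" in adata.obs \
        else np.zeros(adata.n_obs, dtype=int)
    sf = pooled_size_factors(adata.X, batches, pool_sizes)
    rescale = _batch_rescale(sp.csr_matrix(adata.X), sf, batches)
    return NormalizationModel(
        size_factors=pd.Series(sf, index=adata.obs_names),
        batch_rescale=rescale, pool_sizes=tuple(pool_sizes))


def log_normalize(counts, model: NormalizationModel,
                  batches=None) -> sp.csr_matrix:
    """``log2(count / (size_factor * batch_rescale) + 1)``, sparse-preserving."""
    X = sp.csr_matrix(counts, dtype=float)
    sf = model.size_factors.to_numpy(dtype=float).copy()
    if np.any(sf <= 0):
        raise ValueError("size factors must be positive")
    if batches is not None and model.batch_rescale:
        resc = np.array([model.batch_rescale.get(b, 1.0) for b in
                         np.asarray(batches)])
        sf = sf * resc
    Xn = sp.diags(1.0 / sf) @ X
    Xn = Xn.log1p()
    Xn = Xn.multiply(1.0 / np.log(2.0))
    return sp.csr_matrix(Xn)


def _variance_trend(mean: np.ndarray, var: np.ndarray,
                    span: float = 0.3) -> np.ndarray:
    fitted = lowess(var, mean, frac=span, return_sorted=False)
    return np.maximum(fitted, 0.0)


def select_hvgs(logexpr, gene_names, gene_flags: pd.DataFrame | None = None,
                batches=None, span: float = 0.3
                ) -> tuple[list[str], pd.DataFrame]:
    """Variance-decomposition HVGs.

    Returns the HVG ids ordered by decreasing biological residual, and the
    per-gene decomposition table (mean, total variance, technical trend,
    biological residual, is_hvg). With ``batches`` given, decompositions are
    computed per batch and averaged with residual-df weights. Ribosomal and
    mitochondrial flagged genes never enter the HVG set.
    """
    X = sp.csr_matrix(logexpr)
    gene_names = list(gene_names)
    if batches is None:
        batches = np.zeros(X.shape[0], dtype=int)
    batches = np.asarray(batches)
    uniq = pd.unique(batches)
    means, totals, techs, dfs = [], [], [], []
    for b in uniq:
        idx = np.where(batches == b)[0]
        Xb = X[idx]
        m = np.asarray(Xb.mean(axis=0)).ravel()
        m2 = np.asarray(Xb.power(2).mean(axis=0)).ravel()
        nb = idx.size
        v = (m2 - m ** 2) * nb / max(nb - 1, 1)
        tech = _variance_trend(m, v, span)
        means.append(m)
        totals.append(v)
        techs.append(tech)
        dfs.append(max(nb - 1, 1))
    w = np.asarray(dfs, float)
    w = w / w.sum()
    mean = np.einsum("b,bg->g", w, np.vstack(means))
    total = np.einsum("b,bg->g", w, np.vstack(totals))
    tech = np.einsum("b,bg->g", w, np.vstack(techs))
    bio = total - tech
    decomp = pd.DataFrame({
        "mean": mean, "total_var": total, "trend_fit": tech,
        "bio_residual": bio,
    }, index=gene_names)
    excluded = np.zeros(len(gene_names), dtype=bool)
    if gene_flags is not None:
        for col in ("is_ribo", "is_mito"):
            if col in gene_flags:
                excluded |= gene_flags[col].to_numpy(dtype=bool)
    decomp["excluded"] = excluded
    decomp["is_hvg"] = (bio > 0) & ~excluded
    if decomp["is_hvg"].sum() == 0 and excluded.all():
        raise ValueError("all genes are flag-excluded; no HVGs possible")
    hvgs = decomp[decomp["is_hvg"]].sort_values(
        "bio_residual", ascending=False).index.tolist()
    return hvgs, decomp
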