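"""Transcriptional ordering of samples along a latent progression axis.

Samples are pseudo-bulked (UMI counts summed per sample), normalised with
trimmed-mean-of-M-values (TMM) factors, log-CPM transformed and subjected
to a gene-centred PCA. PC1 is taken as the progression axis; its sign is
anchored so that designated early (wild-type-like) samples sit low, and it
is min-max scaled to [0, 1] across the training samples. Stages are
equal-width bins of the scaled axis (with an explicit-boundary override);
held-out samples can be projected into the trained space.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

__all__ = [
    "StagingResult",
    "pseudobulk",
    "tmm_factors",
    "staging_pca",
    "bin_stages",
    "project_samples",
]


@dataclass
class StagingResult:
    pseudobulk: pd.DataFrame            # samples x genes raw summed counts
    tmm: pd.Series                      # per-sample TMM factor
    genes: pd.Index                     # genes entering the PCA
    gene_means: np.ndarray              # centering means on the logCPM scale
    loadings: np.ndarray                # components x genes (orthonormal)
    pc1: pd.Series                      # sign-anchored
    pc1_scaled: pd.Series               # min-max to [0, 1]
    pc1_min: float
    pc1_max: float
    explained_variance: np.ndarray
    ref_sample: str                     # TMM reference for projection
    tmm_norm_const: float = 1.0         # geometric-mean renormalisation
    stages: pd.Series | None = None
    trim_m: float = 0.30
    trim_a: float = 0.05


def pseudobulk(adata, sample_key: str = "sample") -> pd.DataFrame:
    """Sum UMI counts over each sample's cells -> samples x genes table."""
    if sample_key not in adata.obs:
        raise ValueError(f"missing obs column {sample_key!r}")
    samples = adata.obs[sample_key].astype(str).to_numpy()
    X = sp.csr_matrix(adata.X)
    uniq = pd.unique(samples)
    rows = []
    for s in uniq:
        idx = samples == s
        if idx.sum() == 0:
            warnings.warn(f"sample {s!r} has no cells; dropped")
            continue
        rows.append(np.asarray(X[idx].sum(axis=0)).ravel())
    return pd.DataFrame(rows, index=uniq, columns=adata.var_names)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, trim_m: float,
              trim_a: float) -> float:
    """TMM factor of one library against the reference (Robinson-Oshlack)."""
    lib_o, lib_r = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    if not both.any():
        warnings.warn("no genes co-expressed with reference; factor set to 1")
        return 1.0
    o = obs[both] / lib_o
    r = ref[both] / lib_r
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    # asymptotic (delta-method) variance of M; weights are its inverse
    v = (lib_o - obs[both]) / (lib_o * obs[both]) \
        + (lib_r - ref[both]) / (lib_r * ref[both])
    n = M.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rM = rankdata(M)
    rA = rankdata(A)
    keep = (rM >= lo_m) & (rM <= hi_m) & (rA >= lo_a) & (rA <= hi_a)
    if not keep.any():
        warnings.warn("trimming removed all genes; factor set to 1")
        return 1.0
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(pb: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05,
                ref: str | None = None,
                renormalize: bool = True) -> tuple[pd.Series, str]:
    """TMM normalisation factors for a pseudo-bulk matrix.

    M-values against the reference sample on doubly-expressed genes are
    trimmed (30% on M, 5% on A by default) and averaged with
    inverse-asymptotic-variance weights; ``factor = 2**weighted_mean``.
    Factors are renormalised to geometric mean 1. When ``ref`` is None, the
    reference is the sample whose upper quartile of relative expression is
    closest to the mean upper quartile.

    Returns ``(factors, reference_sample)``.
    """
    if pb.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    counts = pb.to_numpy(dtype=float)
    lib = counts.sum(axis=1)
    if np.any(lib <= 0):
        raise ValueError("all samples must have positive library size")
    if ref is None:
        f75 = np.array([np.quantile(row / l, 0.75)
                        for row, l in zip(counts, lib)])
        ref = pb.index[int(np.argmin(np.abs(f75 - f75.mean())))]
    ref_row = pb.loc[ref].to_numpy(dtype=float)
    factors = np.array([
        1.0 if s == ref else _tmm_pair(counts[i], ref_row, trim_m, trim_a)
        for i, s in enumerate(pb.index)])
    if renormalize:
        factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=pb.index), str(ref)


def _log_cpm(counts: np.ndarray, eff_lib: np.ndarray) -> np.ndarray:
    return np.log2(counts / eff_lib[:, None] * 1e6 + 1.0)


def staging_pca(pb: pd.DataFrame, tmm: pd.Series | None = None,
                anchor_samples=(), min_cpm: float = 1.0,
                min_samples: int = 2, trim_m: float = 0.30,
                trim_a: float = 0.05) -> StagingResult:
    """PCA staging of pseudo-bulk profiles.

    Expression enters as ``log2(CPM + 1)`` with TMM-adjusted library sizes,
    restricted to genes with CPM > ``min_cpm`` in at least ``min_samples``
    samples. PC1's sign is flipped, if needed, so the mean PC1 of
    ``anchor_samples`` (samples known to be early/wild-type-like) lies below
    the overall mean; the scaled axis maps the extreme samples to 0 and 1.
    """
    if pb.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    if len(anchor_samples) == 0:
        raise ValueError("anchor_samples must be non-empty")
    if tmm is None:
        raw, ref = tmm_factors(pb, trim_m, trim_a, renormalize=False)
        norm_const = float(np.exp(np.mean(np.log(raw))))
        tmm = raw / norm_const
    else:
        _, ref = tmm_factors(pb, trim_m, trim_a)
        tmm = tmm.reindex(pb.index)
        norm_const = 1.0
    counts = pb.to_numpy(dtype=float)
    lib = counts.sum(axis=1)
    eff = lib * tmm.to_numpy()
    cpm = counts / eff[:, None] * 1e6
    keep = (cpm > min_cpm).sum(axis=0) >= min_samples
    genes = pb.columns[keep]
    logcpm = _log_cpm(counts[:, keep], eff)
    gene_means = logcpm.mean(axis=0)
    Xc = logcpm - gene_means
    if np.allclose(Xc, 0):
        raise ValueError("no latent axis: identical pseudo-bulk profiles")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    pc_scores = Xc @ Vt.T
    pc1 = pc_scores[:, 0]
    anchors = [a for a in anchor_samples if a in pb.index]
    if not anchors:
        raise ValueError("no anchor sample found in the pseudo-bulk matrix")
    a_idx = [pb.index.get_loc(a) for a in anchors]
    if pc1[a_idx].mean() > pc1.mean():
        Vt = -Vt
        pc1 = -pc1
    lo, hi = float(pc1.min()), float(pc1.max())
    pc1_scaled = (pc1 - lo) / (hi - lo)
    return StagingResult(
        pseudobulk=pb, tmm=tmm, genes=genes, gene_means=gene_means,
        loadings=Vt, pc1=pd.Series(pc1, index=pb.index),
        pc1_scaled=pd.Series(pc1_scaled, index=pb.index),
        pc1_min=lo, pc1_max=hi,
        explained_variance=S ** 2 / max(pb.shape[0] - 1, 1),
        ref_sample=ref, tmm_norm_const=norm_const,
        trim_m=trim_m, trim_a=trim_a)


def bin_stages(result: StagingResult, n_bins: int = 4,
               boundaries=None, tumour_samples=()) -> pd.Series:
    """Assign ordinal stages 1..n_bins along the scaled PC1 axis.

    Default bins are equal-width on [0, 1]; explicit inner ``boundaries``
    override them. Samples listed in ``tumour_samples`` bypass binning and
    receive the label "tumour".
    """
    v = result.pc1_scaled
    if boundaries is not None:
        b = np.asarray(boundaries, dtype=float)
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        stage_num = np.searchsorted(b, v.to_numpy(), side="right") + 1
    else:
        stage_num = np.minimum(
            np.floor(v.to_numpy() * n_bins).astype(int) + 1, n_bins)
    labels = pd.Series([str(s) for s in stage_num], index=v.index)
    for t in tumour_samples:
        if t in labels.index:
            labels.loc[t] = "tumour"
    result.stages = labels
    return labels


def project_samples(new_pb: pd.DataFrame,
                    result: StagingResult) -> pd.DataFrame:
    """Project held-out pseudo-bulk samples onto the trained staging axis.

    Each new sample gets a TMM factor against the training reference,
    log-CPM transformation, centering by the training gene means and
    projection on the training loadings; the scaled value uses the training
    min/max and may fall outside [0, 1]. Genes absent from the new samples
    are imputed as zero (with a warning); below 50% overlap is an error.
    """
    genes = result.genes
    overlap = new_pb.columns.intersection(genes)
    if len(overlap) < 0.5 * len(genes):
        raise ValueError("fewer than 50% of training genes present")
    if len(overlap) < len(genes):
        warnings.warn(f"{len(genes) - len(overlap)} training genes missing "
                      "from the new samples; imputed as 0")
    ref_row = result.pseudobulk.loc[result.ref_sample].to_numpy(dtype=float)
    ref_cols = result.pseudobulk.columns
    rows = []
    for s in new_pb.index:
        full = pd.Series(0.0, index=ref_cols)
        common = new_pb.columns.intersection(ref_cols)
        full[common] = new_pb.loc[s, common].astype(float)
        obs = full.to_numpy()
        f = _tmm_pair(obs, ref_row, result.trim_m, result.trim_a) \
            if obs.sum() > 0 else 1.0
        f = f / result.tmm_norm_const
        eff = max(obs.sum(), 1.0) * f
        sub = full[genes].to_numpy()
        logcpm = np.log2(sub / eff * 1e6 + 1.0)
        pc1 = float((logcpm - result.gene_means) @ result.loadings[0])
        rows.append((s, pc1, (pc1 - result.pc1_min)
                     / (result.pc1_max - result.pc1_min)))
    return pd.DataFrame(rows, columns=["sample", "pc1", "pc1_scaled"]) \
        .set_index("sample")
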