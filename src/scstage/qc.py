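"""Per-cell quality metrics and MAD-based outlier filtering.

Four rules, evaluated per batch by default:

* genes detected outside median +/- 3 MAD (log1p scale),
* total UMIs outside median +/- 3 MAD (log1p scale),
* mitochondrial fraction above median + 5 MAD,
* detection-trend residual below median - 6 MAD, where the detection trend
  is a cubic spline regression of log genes-detected on log total UMIs.

Thresholds can be frozen and re-applied, which makes filtering idempotent.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import BSpline

from .statcore import MadRule, fit_mad_rule

__all__ = [
    "QCRules",
    "QCThresholds",
    "compute_cell_metrics",
    "detection_trend_residuals",
    "estimate_thresholds",
    "apply_qc",
    "run_qc",
]


@dataclass(frozen=True)
class QCRules:
    """MAD multipliers of the four filtering rules; ``None`` disables a rule."""

    k_genes: float | None = 3.0
    k_umi: float | None = 3.0
    k_mito_upper: float | None = 5.0
    k_residual_lower: float | None = 6.0
    spline_df: int = 5
    per_batch: bool = True


@dataclass
class QCThresholds:
    """Frozen per-batch MAD rules, re-applicable without re-estimation."""

    rules: QCRules
    genes: dict[str, MadRule] = field(default_factory=dict)
    umi: dict[str, MadRule] = field(default_factory=dict)
    mito: dict[str, MadRule] = field(default_factory=dict)
    residual: dict[str, MadRule] = field(default_factory=dict)


def compute_cell_metrics(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell QC table: UMIs, genes detected, mitochondrial fraction.

    Requires mito-flagged genes in ``adata.var['is_mito']``; if none are
    flagged the mitochondrial fraction is 0 with a warning.
    """
    X = sp.csr_matrix(adata.X)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    if "is_mito" in adata.var and adata.var["is_mito"].any():
        mito = np.asarray(
            X[:, adata.var["is_mito"].to_numpy()].sum(axis=1)).ravel()
    else:
        warnings.warn("no mitochondrial genes flagged; pct_mito set to 0")
        mito = np.zeros(adata.n_obs)
    if np.any(n_umi == 0):
        warnings.warn("cells with zero total UMIs present")
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_umi > 0, mito / np.maximum(n_umi, 1), 0.0)
    qc = pd.DataFrame({
        "n_umi": n_umi.astype(int),
        "n_genes_detected": n_genes.astype(int),
        "pct_mito": pct_mito,
    }, index=adata.obs_names)
    for key in ("sample", "batch"):
        if key in adata.obs:
            qc[key] = adata.obs[key].to_numpy()
    return qc


def _spline_design(x: np.ndarray, knots_x: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline design matrix with interior knots at quantiles of knots_x."""
    degree = 3
    n_interior = max(df - degree - 1, 0)
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(knots_x, qs)
    else:
        interior = np.array([])
    lo, hi = knots_x.min(), knots_x.max()
    pad = max(hi - lo, 1e-9) * 1e-6
    t = np.concatenate([
        np.repeat(lo - pad, degree + 1), interior,
        np.repeat(hi + pad, degree + 1)])
    return BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()


def detection_trend_residuals(n_genes: np.ndarray, n_umi: np.ndarray,
                              spline_df: int = 5) -> np.ndarray:
    """Residuals of a cubic spline fit of log genes-detected on log UMIs.

    Both variables enter on the log scale; knots sit at quantiles of the
    UMI distribution. Residual = observed - fitted.
    """
    n_genes = np.asarray(n_genes, dtype=float)
    n_umi = np.asarray(n_umi, dtype=float)
    if np.any(n_umi <= 0):
        raise ValueError("all cells must have positive total UMIs")
    if n_genes.size < max(spline_df + 2, 20):
        raise ValueError("too few cells to fit the detection trend")
    x = np.log(n_umi)
    y = np.log1p(n_genes)
    B = _spline_design(x, x, spline_df)
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    return y - B @ coef


def estimate_thresholds(qc: pd.DataFrame,
                        rules: QCRules = QCRules()) -> QCThresholds:
    """Estimate (and freeze) the MAD rules, per batch unless disabled."""
    thr = QCThresholds(rules=rules)
    if rules.per_batch and "batch" in qc:
        groups = {str(b): qc.index[qc["batch"] == b] for b in
                  pd.unique(qc["batch"])}
    else:
        groups = {"__all__": qc.index}
    for b, idx in groups.items():
        sub = qc.loc[idx]
        if rules.k_genes is not None:
            thr.genes[b] = fit_mad_rule(sub["n_genes_detected"],
                                        rules.k_genes, rules.k_genes,
                                        log_transform=True)
        if rules.k_umi is not None:
            thr.umi[b] = fit_mad_rule(sub["n_umi"], rules.k_umi, rules.k_umi,
                                      log_transform=True)
        if rules.k_mito_upper is not None:
            thr.mito[b] = fit_mad_rule(sub["pct_mito"], None,
                                       rules.k_mito_upper)
        if rules.k_residual_lower is not None:
            res = detection_trend_residuals(
                sub["n_genes_detected"].to_numpy(),
                np.maximum(sub["n_umi"].to_numpy(), 1),
                spline_df=rules.spline_df)
            thr.residual[b] = fit_mad_rule(res, rules.k_residual_lower, None)
    return thr


def apply_qc(qc: pd.DataFrame, rules: QCRules | None = None,
             thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Evaluate the filtering rules and return the QC table with flags.

    Pass ``thresholds`` (from :func:`estimate_thresholds`) to re-apply a
    frozen rule set; otherwise thresholds are estimated from ``qc`` itself.
    Adds boolean columns ``flag_*``, ``detection_residual`` and ``kept``
    (the conjunction of not-flagged).
    """
    if thresholds is None:
        thresholds = estimate_thresholds(qc, rules or QCRules())
    rules = thresholds.rules
    out = qc.copy()
    for col in ("flag_genes", "flag_umi", "flag_mito", "flag_residual"):
        out[col] = False
    out["detection_residual"] = np.nan
    if rules.per_batch and "batch" in qc:
        groups = {str(b): qc.index[qc["batch"] == b] for b in
                  pd.unique(qc["batch"])}
    else:
        groups = {"__all__": qc.index}
    for b, idx in groups.items():
        sub = out.loc[idx]
        if b in thresholds.genes:
            out.loc[idx, "flag_genes"] = thresholds.genes[b].flags(
                np.log1p(sub["n_genes_detected"].to_numpy(dtype=float)))
        if b in thresholds.umi:
            out.loc[idx, "flag_umi"] = thresholds.umi[b].flags(
                np.log1p(sub["n_umi"].to_numpy(dtype=float)))
        if b in thresholds.mito:
            out.loc[idx, "flag_mito"] = thresholds.mito[b].flags(
                sub["pct_mito"].to_numpy())
        if b in thresholds.residual:
            res = detection_trend_residuals(
                sub["n_genes_detected"].to_numpy(),
                np.maximum(sub["n_umi"].to_numpy(), 1),
                spline_df=rules.spline_df)
            out.loc[idx, "detection_residual"] = res
            out.loc[idx, "flag_residual"] = thresholds.residual[b].flags(res)
    out["kept"] = ~(out["flag_genes"] | out["flag_umi"]
                    | out["flag_mito"] | out["flag_residual"])
    return out


def run_qc(adata: ad.AnnData, rules: QCRules = QCRules()
           ) -> tuple[pd.DataFrame, QCThresholds]:
    """Convenience: metrics + threshold estimation + flagging in one call."""
    qc = compute_cell_metrics(adata)
    thresholds = estimate_thresholds(qc, rules)
    return apply_qc(qc, thresholds=thresholds), thresholds
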