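"""Shared statistical primitives.

MAD outlier rules, Huber robust regression with a robust slope test,
Benjamini-Hochberg adjustment, Spearman correlation and the qPCR
delta-delta-Ct fold change. These are the building blocks used by the
QC, differential-abundance and differential-correlation stages.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MAD_CONSTANT",
    "MadRule",
    "RobustFit",
    "mad_outliers",
    "scaled_mad",
    "huber_fit",
    "robust_slope_test",
    "bh_adjust",
    "spearman_rho",
    "ddct_fold_change",
]

#: Normal-consistency scaling of the median absolute deviation.
MAD_CONSTANT = 1.4826


@dataclass(frozen=True)
class MadRule:
    """A median +/- k*MAD decision rule.

    One-sided rules leave the unused multiplier ``None``, which makes the
    corresponding bound infinite.
    """

    center: float
    mad: float
    k_lower: float | None = None
    k_upper: float | None = None

    @property
    def lower(self) -> float:
        if self.k_lower is None:
            return -np.inf
        return self.center - self.k_lower * self.mad

    @property
    def upper(self) -> float:
        if self.k_upper is None:
            return np.inf
        return self.center + self.k_upper * self.mad

    def flags(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v < self.lower) | (v > self.upper)


def scaled_mad(values: np.ndarray) -> float:
    """Median absolute deviation scaled by 1.4826 (normal consistency)."""
    v = np.asarray(values, dtype=float)
    return MAD_CONSTANT * float(np.median(np.abs(v - np.median(v))))


def fit_mad_rule(
    values: np.ndarray,
    k_lower: float | None = None,
    k_upper: float | None = None,
    log_transform: bool = False,
) -> MadRule:
    """Estimate a :class:`MadRule` from data.

    With ``log_transform`` the rule lives on the log1p scale; callers must
    transform values consistently before applying it (``mad_outliers`` does).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot fit a MAD rule on an empty vector")
    if np.all(np.isnan(v)):
        raise ValueError("all values are NaN")
    if log_transform:
        v = np.log1p(v)
    return MadRule(center=float(np.median(v)), mad=scaled_mad(v),
                   k_lower=k_lower, k_upper=k_upper)


def mad_outliers(
    values: np.ndarray,
    k_lower: float | None = None,
    k_upper: float | None = None,
    log_transform: bool = False,
    rule: MadRule | None = None,
) -> np.ndarray:
    """Flag values outside median +/- k*MAD.

    Parameters
    ----------
    values
        Finite numeric vector (NaN allowed only if not all-NaN).
    k_lower, k_upper
        MAD multipliers; ``None`` disables the corresponding side.
    log_transform
        Evaluate the rule on ``log1p(values)``.
    rule
        A pre-fitted (frozen) rule; when given, thresholds are *not*
        re-estimated from ``values``, enabling idempotent filtering.

    Returns
    -------
    Boolean array, True for outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot flag outliers on an empty vector")
    if np.all(np.isnan(v)):
        raise ValueError("all values are NaN")
    if rule is None:
        rule = fit_mad_rule(v, k_lower, k_upper, log_transform=log_transform)
    if log_transform:
        v = np.log1p(v)
    return rule.flags(v)


# ---------------------------------------------------------------------------
# Huber robust regression
# ---------------------------------------------------------------------------

@dataclass
class RobustFit:
    """Result of an IRLS Huber regression of y on a single predictor."""

    slope: float
    intercept: float
    robust_scale: float
    weights: np.ndarray
    iterations: int
    converged: bool
    tuning_k: float = 1.345
    x: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)

    @property
    def residuals(self) -> np.ndarray:
        return self.y - (self.intercept + self.slope * self.x)


def huber_fit(
    x: np.ndarray,
    y: np.ndarray,
    tuning_k: float = 1.345,
    max_it: int = 100,
    tol: float = 1e-10,
) -> RobustFit:
    """Huber M-estimation of a simple linear regression by IRLS.

    The scale is re-estimated each iteration as the scaled MAD of the
    residuals; weights are ``min(1, k*s/|r|)``. With ``tuning_k`` large the
    estimate coincides with ordinary least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: x is constant")

    # start from OLS
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.ones(n)
    converged = False
    it = 0
    for it in range(1, max_it + 1):
        r = y - X @ beta
        s = scaled_mad(r)
        if s <= 0:
            # exact fit (or >50% of residuals identical): weights stay 1
            converged = True
            break
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, tuning_k * s / np.abs(r))
        w[~np.isfinite(w)] = 1.0  # zero residual -> full weight
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        delta = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    r = y - X @ beta
    s = scaled_mad(r)
    return RobustFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        robust_scale=float(s),
        weights=w,
        iterations=it,
        converged=converged,
        tuning_k=tuning_k,
        x=x,
        y=y,
    )


def robust_slope_test(fit: RobustFit, x: np.ndarray | None = None,
                      y: np.ndarray | None = None) -> float:
    """Robust Wald test of slope == 0 for a Huber fit.

    The slope variance uses the Huber asymptotic sandwich
    ``[sum(psi^2) / (n-p)] / [mean(psi')]^2 * (X'X)^{-1}`` with Huber's
    small-sample correction factor, and the statistic is referred to a
    t distribution with n-2 degrees of freedom.
    """
    x = fit.x if x is None else np.asarray(x, dtype=float)
    y = fit.y if y is None else np.asarray(y, dtype=float)
    n = x.size
    p = 2
    if not fit.converged:
        warnings.warn("robust fit did not converge; p-value may be unreliable",
                      RuntimeWarning)
    r = y - (fit.intercept + fit.slope * x)
    s = fit.robust_scale
    if s <= 0:
        # perfect fit: slope exactly determined
        return 1.0 if fit.slope == 0 else np.finfo(float).tiny
    u = r / s
    k = fit.tuning_k
    psi = np.clip(u, -k, k)          # Huber psi
    dpsi = (np.abs(u) <= k).astype(float)
    m1 = dpsi.mean()
    if m1 <= 0:
        return 1.0
    # Huber's 1981 correction for the proposal-2 style variance estimate
    kappa = 1.0 + (p / n) * np.var(dpsi) / (m1 ** 2)
    num = (s ** 2) * np.sum(psi ** 2) / (n - p)
    var_common = kappa ** 2 * num / (m1 ** 2)
    X = np.column_stack([np.ones(n), x])
    xtx_inv = np.linalg.inv(X.T @ X)
    se_slope = np.sqrt(var_common * xtx_inv[1, 1])
    if se_slope == 0:
        return 1.0 if fit.slope == 0 else np.finfo(float).tiny
    t_stat = fit.slope / se_slope
    pval = 2.0 * stats.t.sf(np.abs(t_stat), df=n - p)
    return float(min(max(pval, np.finfo(float).tiny), 1.0))


# ---------------------------------------------------------------------------
# Multiple testing, correlation, qPCR
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min_{j >= rank(i)} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def spearman_rho(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman correlation with mid-ranks for ties.

    Returns NaN (an explicit "undefined" marker, not 0) when either rank
    vector has zero variance; the caller decides how to handle it.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length vectors with at least 3 values")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        return float("nan")
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the delta-delta-Ct method: 2**(-ddCt).

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v) or v <= 0:
            raise ValueError("Ct values must be finite and positive")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
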