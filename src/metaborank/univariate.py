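"""Per-feature covariate-adjusted logistic screens with multiple-testing rankings.

For every metabolite feature x_j a logistic regression of the binary outcome
on {intercept, x_j, age, sex} is fit by Newton-Raphson, batched across
features for speed; the Wald two-sided p-value of the feature coefficient is
the screen statistic.  Bonferroni and Benjamini-Hochberg (BH step-up FDR)
adjustments give two rankings: ascending adjusted p, ties broken by the raw
p-value, residual ties by feature id so reruns are bit-identical.

Features whose fit is degenerate (constant column) or fails to converge are
scored missing and receive the imputed rank (total feature count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .containers import AbundanceMatrix, MethodRanking, SampleMetadata

#: |beta| beyond this (on standardized features) is treated as separation.
SEPARATION_BETA = 15.0


@dataclass
class UnivariateScan:
    """Batched per-feature logistic fit results."""

    feature_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    raw_p: np.ndarray          # NaN where the fit failed
    converged: np.ndarray
    separated: np.ndarray

    @property
    def fitted(self) -> np.ndarray:
        return np.isfinite(self.raw_p)


def _newton_batch(y: np.ndarray, D: np.ndarray, max_iter: int = 50,
                  tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton-Raphson logistic fits for a (p, n, k) stack of design matrices.

    Returns (params (p, k), se of column 1, converged flags).  A tiny ridge
    on the Hessian guards against exactly singular steps; convergence is a
    max-gradient criterion.
    """
    p, n, k = D.shape
    params = np.zeros((p, k))
    converged = np.zeros(p, dtype=bool)
    active = np.arange(p)
    for _ in range(max_iter):
        Da = D[active]
        eta = np.einsum("pnk,pk->pn", Da, params[active])
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = np.einsum("pnk,pn->pk", Da, y[None, :] - mu)
        H = np.einsum("pnk,pn,pnl->pkl", Da, w, Da)
        H[:, np.arange(k), np.arange(k)] += 1e-10
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        params[active] += step
        done = np.max(np.abs(grad), axis=1) < tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    # standard errors from the observed information at the solution
    eta = np.clip(np.einsum("pnk,pk->pn", D, params), -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = np.einsum("pnk,pn,pnl->pkl", D, w, D)
    H[:, np.arange(k), np.arange(k)] += 1e-10
    cov = np.linalg.inv(H)
    se = np.sqrt(np.maximum(cov[:, 1, 1], 0.0))
    return params, se, converged


def fit_univariate_logistic(y: np.ndarray, x: np.ndarray,
                            covariates: np.ndarray) -> tuple[float, float, float]:
    """Single-feature adjusted logistic fit.

    Maximum-likelihood fit of ``y`` on ``{intercept, x, covariates}``;
    returns the feature coefficient, its standard error, and the two-sided
    Wald p-value.  Raises on a single-class outcome or a constant feature.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if np.std(x) == 0:
        raise ValueError("feature is constant; no coefficient is identifiable")
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != len(y):
        cov = cov.T
    D = np.column_stack([np.ones_like(y), x, cov])[None, :, :]
    params, se, converged = _newton_batch(y, D)
    if not converged[0]:
        raise RuntimeError("logistic fit did not converge")
    beta = float(params[0, 1])
    s = float(se[0])
    z = beta / s if s > 0 else np.inf
    return beta, s, float(2.0 * norm.sf(abs(z)))


def univariate_scan(X: AbundanceMatrix, meta: SampleMetadata,
                    batch_size: int = 256) -> UnivariateScan:
    """Adjusted logistic screen of every feature, batched across features."""
    meta = meta.aligned_to(X)
    y = meta.outcome.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    age = meta.age - meta.age.mean()
    sex = meta.sex_indicator
    n, p = X.values.shape
    ones = np.ones(n)

    beta = np.full(p, np.nan)
    se = np.full(p, np.nan)
    raw_p = np.full(p, np.nan)
    conv = np.zeros(p, dtype=bool)

    sd = X.values.std(axis=0)
    valid = np.flatnonzero((sd > 0) & ~X.degenerate)
    for start in range(0, valid.size, batch_size):
        idx = valid[start:start + batch_size]
        xs = X.values[:, idx]
        D = np.empty((idx.size, n, 4))
        D[:, :, 0] = ones
        D[:, :, 1] = xs.T
        D[:, :, 2] = age
        D[:, :, 3] = sex
        params, ses, ok = _newton_batch(y, D)
        beta[idx] = params[:, 1]
        se[idx] = ses
        conv[idx] = ok

    separated = conv & (np.abs(beta) > SEPARATION_BETA)
    fitted = conv & (se > 0)
    z = np.where(fitted, beta / np.where(se > 0, se, 1.0), np.nan)
    raw_p[fitted] = 2.0 * norm.sf(np.abs(z[fitted]))
    return UnivariateScan(list(X.feature_ids), beta, se, raw_p, conv, separated)


def bonferroni_adjust(raw_p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni family-wise adjustment: ``min(1, m * p)``."""
    p = np.asarray(raw_p, dtype=float)
    _check_unit_interval(p)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def bh_fdr_adjust(raw_p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, q_(i) = p_(i) * m / i, enforce monotone non-decreasing
    from the largest index down, cap at 1, return in the original order.
    """
    p = np.asarray(raw_p, dtype=float)
    _check_unit_interval(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _check_unit_interval(p: np.ndarray) -> None:
    finite = p[np.isfinite(p)]
    if finite.size and (np.any(finite < 0) or np.any(finite > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite")


def rank_by_pvalues(adjusted_p: np.ndarray, raw_p: np.ndarray,
                    feature_ids: list[str], method: str) -> MethodRanking:
    """Rank ascending by (adjusted p, raw p), residual ties by feature id.

    Features with a missing (NaN) p-value — degenerate or non-converged
    fits — are imputed at rank = total feature count.
    """
    adjusted_p = np.asarray(adjusted_p, dtype=float)
    raw_p = np.asarray(raw_p, dtype=float)
    if not (len(adjusted_p) == len(raw_p) == len(feature_ids)):
        raise ValueError("adjusted_p, raw_p and feature_ids must align")
    p_total = len(feature_ids)
    scored = np.isfinite(adjusted_p) & np.isfinite(raw_p)
    order = sorted(np.flatnonzero(scored),
                   key=lambda i: (adjusted_p[i], raw_p[i], feature_ids[i]))
    rank = np.full(p_total, p_total, dtype=int)
    for r, i in enumerate(order, start=1):
        rank[i] = r
    score = np.where(scored, adjusted_p, np.nan)
    return MethodRanking(method, list(feature_ids), score, rank, ~scored)


def rank_bonferroni(scan: UnivariateScan) -> MethodRanking:
    """Bonferroni ranking; m = number of features with a computed p-value."""
    m = int(scan.fitted.sum())
    adj = np.full_like(scan.raw_p, np.nan)
    adj[scan.fitted] = bonferroni_adjust(scan.raw_p[scan.fitted], m)
    return rank_by_pvalues(adj, scan.raw_p, scan.feature_ids, "bonferroni")


def rank_fdr(scan: UnivariateScan) -> MethodRanking:
    """BH-FDR ranking over the features with a computed p-value."""
    adj = np.full_like(scan.raw_p, np.nan)
    adj[scan.fitted] = bh_fdr_adjust(scan.raw_p[scan.fitted])
    return rank_by_pvalues(adj, scan.raw_p, scan.feature_ids, "fdr")
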