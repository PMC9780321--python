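"""Lightweight random-intercept linear model via profiled maximum likelihood.

The model is y = X b + Z delta + eps with one random intercept per individual,
delta_u ~ N(0, tau^2), eps ~ N(0, sigma^2).  For a given variance ratio
rho = tau^2 / sigma^2 the marginal covariance is sigma^2 (I + rho Z Z'),
whose inverse is block diagonal with per-individual Sherman-Morrison blocks
I - rho / (1 + n_u rho) J.  Both the GLS estimate and the profiled
log-likelihood therefore reduce to per-individual sums, and only a 1-D
optimization over log(rho) remains.

A fixed-effects fallback is used when the variance ratio estimate lands on
the boundary of the search interval: per-individual centering (upper
boundary, the random intercepts degenerate to fixed ones) or plain OLS
(lower boundary, no individual variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["RandomInterceptFit", "fit_random_intercept"]

_LOG_RHO_LO, _LOG_RHO_HI = -12.0, 12.0


@dataclass
class RandomInterceptFit:
    beta: np.ndarray
    cov_beta: np.ndarray  # covariance of the fixed-effect estimates
    sigma2: float
    tau2: float
    fitted: np.ndarray  # marginal (fixed-effects-only) prediction X @ beta
    kind: str  # "random-intercept" | "ols" | "centered"
    n_obs: int
    n_individuals: int
    n_params: int

    @property
    def residual_df(self) -> int:
        """Conservative residual df: N - p - (#individuals - 1)."""
        return self.n_obs - self.n_params - (self.n_individuals - 1)


def _gls_pieces(X: np.ndarray, y: np.ndarray, ind_slices: list[np.ndarray], rho: float):
    """X'V*inv X, X'V*inv y, y'V*inv y and log|V*| for V* = I + rho Z Z'."""
    xtx = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)
    logdet = 0.0
    for rows in ind_slices:
        n_u = len(rows)
        w = rho / (1.0 + n_u * rho)
        sx = X[rows].sum(axis=0)
        sy = float(y[rows].sum())
        xtx = xtx - w * np.outer(sx, sx)
        xty = xty - w * sx * sy
        yty -= w * sy * sy
        logdet += np.log1p(n_u * rho)
    return xtx, xty, yty, logdet


def fit_random_intercept(
    y: np.ndarray, X: np.ndarray, individuals: np.ndarray
) -> RandomInterceptFit | None:
    """ML fit of the random-intercept model; None when degenerate.

    ``individuals`` is a per-observation label array; rows with non-finite y
    must already be removed.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p or np.linalg.matrix_rank(X) < p:
        return None
    labels = np.unique(individuals)
    ind_slices = [np.flatnonzero(individuals == u) for u in labels]
    n_ind = len(labels)

    def neg2ll(log_rho: float) -> float:
        rho = np.exp(log_rho)
        xtx, xty, yty, logdet = _gls_pieces(X, y, ind_slices, rho)
        try:
            beta = np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError:
            return np.inf
        q = yty - float(xty @ beta)
        if q <= 0:
            return np.inf
        return n * np.log(q / n) + logdet

    opt = minimize_scalar(
        neg2ll, bounds=(_LOG_RHO_LO, _LOG_RHO_HI), method="bounded",
        options={"xatol": 1e-3},
    )
    log_rho = float(opt.x)

    if log_rho >= _LOG_RHO_HI - 0.5:
        return _centered_fallback(y, X, ind_slices, n_ind)
    if log_rho <= _LOG_RHO_LO + 0.5:
        rho = 0.0
    else:
        rho = float(np.exp(log_rho))

    xtx, xty, yty, _ = _gls_pieces(X, y, ind_slices, rho)
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return None
    beta = xtx_inv @ xty
    q = yty - float(xty @ beta)
    sigma2 = q / n
    df = n - p - (n_ind - 1)
    if df <= 0:
        return None
    sigma2_unbiased = q / df
    return RandomInterceptFit(
        beta=beta,
        cov_beta=xtx_inv * sigma2_unbiased,
        sigma2=sigma2,
        tau2=rho * sigma2,
        fitted=X @ beta,
        kind="random-intercept" if rho > 0 else "ols",
        n_obs=n,
        n_individuals=n_ind,
        n_params=p,
    )


def _centered_fallback(
    y: np.ndarray, X: np.ndarray, ind_slices: list[np.ndarray], n_ind: int
) -> RandomInterceptFit | None:
    """Per-individual centering: within-individual OLS (fixed baselines)."""
    n, p = X.shape
    yc = y.copy()
    Xc = X.copy()
    for rows in ind_slices:
        yc[rows] -= yc[rows].mean()
        Xc[rows] -= Xc[rows].mean(axis=0)
    # the intercept (and any column constant within individuals) is centered
    # away; keep it estimable by pinning it through the grand mean instead
    keep = np.ptp(Xc, axis=0) > 1e-12
    if not keep.any():
        return None
    beta = np.zeros(p)
    sub = Xc[:, keep]
    if np.linalg.matrix_rank(sub) < sub.shape[1]:
        return None
    coef, *_ = np.linalg.lstsq(sub, yc, rcond=None)
    beta[keep] = coef
    resid = yc - sub @ coef
    df = n - int(keep.sum()) - (n_ind - 1)
    if df <= 0:
        return None
    sigma2 = float(resid @ resid) / df
    cov = np.full((p, p), np.nan)
    cov_sub = np.linalg.inv(sub.T @ sub) * sigma2
    ix = np.flatnonzero(keep)
    cov[np.ix_(ix, ix)] = cov_sub
    # recover the dropped intercept-like terms from the uncentered fit
    fitted = X @ beta
    return RandomInterceptFit(
        beta=beta,
        cov_beta=cov,
        sigma2=sigma2,
        tau2=np.inf,
        fitted=fitted,
        kind="centered",
        n_obs=n,
        n_individuals=n_ind,
        n_params=int(keep.sum()),
    )
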