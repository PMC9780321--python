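"""PolyReg: protein-wise polynomial regression with condition contrasts.

For every protein the model

    y = b0 + sum_j b_j P_j(t) + g0 c + sum_j g_j c P_j(t) + eps,  j = 1..d

is fitted over all samples, with P_j an orthogonal polynomial basis of the
time grid (unit-norm when the study is aligned, raw recursion output when
not) and the condition coded c = +-1/2 so that g_j is the between-condition
difference in the j-th trend coefficient.  The default degree is
d = max{2, min(m - 1, 5)} with m the median timepoint count.  Each condition
coefficient is tested with a two-sided t-test and the module score is
S = min(p_g0, ..., p_gd).

Aligned studies use fixed-effects least squares; non-aligned studies add a
random intercept per individual (profiled ML), with a conservative residual
df of N - #params - (#individuals - 1) for the t-tests.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import qr
from scipy.stats import t as t_dist

from .data import ExpressionMatrix, ModuleResult, StudyDesign
from .mixed import fit_random_intercept
from .regrots import orthogonal_basis

logger = logging.getLogger(__name__)

__all__ = ["polyreg_degree", "polyreg_score"]


def polyreg_degree(median_timepoints: float) -> int:
    """Model degree: max{2, min(m - 1, 5)}."""
    m = float(median_timepoints)
    if m < 2:
        raise ValueError("too few time points: median timepoint count must be >= 2")
    return max(2, min(int(m) - 1, 5))


def _design_matrix(design: StudyDesign, sample_ids: list[str], degree: int):
    table = design.table.set_index("sample_id").loc[sample_ids]
    t = table["timepoint"].to_numpy(dtype=float)
    cond = table["condition"].to_numpy()
    ind = table["individual"].to_numpy()
    c1, _ = design.conditions
    c = np.where(cond == c1, -0.5, 0.5)

    # basis on the distinct time grid, evaluated at each sample's time
    grid = np.array(sorted(np.unique(t)))
    if len(grid) <= degree:
        raise ValueError(
            f"degree too high: degree {degree} needs > {degree} distinct timepoints"
        )
    basis_grid = orthogonal_basis(grid, degree, scale=design.aligned)
    pos = {tp: i for i, tp in enumerate(grid)}
    basis = basis_grid[[pos[tp] for tp in t], :]

    X = np.column_stack(
        [np.ones(len(t)), basis, c, basis * c[:, None]]
    )
    gamma_cols = np.arange(degree + 1) + (degree + 1)
    return X, gamma_cols, ind


def _ols_gamma_pvalues(X: np.ndarray, Y: np.ndarray, gamma_cols: np.ndarray):
    """Two-sided t-tests of the gamma columns for all rows of Y (complete X).

    Rank-deficient designs drop non-estimable columns (pivoted QR); their
    p-values are NaN.
    """
    n, p = X.shape
    n_gamma = len(gamma_cols)
    out_p = np.full((Y.shape[0], n_gamma), np.nan)
    out_b = np.full((Y.shape[0], n_gamma), np.nan)
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, _, piv = qr(X, pivoting=True)
        keep = np.sort(piv[:rank])
    else:
        keep = np.arange(p)
    Xk = X[:, keep]
    df = n - len(keep)
    if df <= 0:
        return out_p, out_b
    xtx_inv = np.linalg.inv(Xk.T @ Xk)
    beta = xtx_inv @ Xk.T @ Y.T  # (#keep, n_proteins)
    resid = Y.T - Xk @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = beta / se
    pv = 2.0 * t_dist.sf(np.abs(tval), df)
    col_of = {c: i for i, c in enumerate(keep)}
    for gi, gc in enumerate(gamma_cols):
        if gc in col_of:
            out_p[:, gi] = pv[col_of[gc]]
            out_b[:, gi] = beta[col_of[gc]]
    return out_p, out_b


def polyreg_score(
    expr: ExpressionMatrix,
    design: StudyDesign,
    degree: int | None = None,
    random_intercept: bool | None = None,
) -> ModuleResult:
    """Per-protein PolyReg score S = min over condition-coefficient p-values."""
    expr.check_samples(design)
    if degree is None:
        degree = polyreg_degree(design.median_timepoints)
    if random_intercept is None:
        random_intercept = not design.aligned

    values = expr.values
    P = values.shape[0]
    X_full, gamma_cols, ind = _design_matrix(design, expr.samples, degree)
    pmat = np.full((P, degree + 1), np.nan)
    gmat = np.full((P, degree + 1), np.nan)

    if not random_intercept:
        obs = np.isfinite(values)
        patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
        for pi, pat in enumerate(patterns):
            rows = np.flatnonzero(pat)
            sel = np.flatnonzero(inverse == pi)
            if len(rows) < 2:
                continue
            pv, bv = _ols_gamma_pvalues(
                X_full[rows], values[np.ix_(sel, rows)], gamma_cols
            )
            pmat[sel] = pv
            gmat[sel] = bv
    else:
        for p in range(P):
            rows = np.flatnonzero(np.isfinite(values[p]))
            if len(rows) < X_full.shape[1] + 2:
                # try a reduced, estimable design below via rank handling
                pass
            X = X_full[rows]
            rank = np.linalg.matrix_rank(X) if len(rows) else 0
            if rank == 0:
                continue
            if rank < X.shape[1]:
                _, _, piv = qr(X, pivoting=True)
                keep = np.sort(piv[:rank])
            else:
                keep = np.arange(X.shape[1])
            fit = fit_random_intercept(values[p, rows], X[:, keep], ind[rows])
            if fit is None or fit.residual_df <= 0:
                continue
            se = np.sqrt(np.diag(fit.cov_beta))
            with np.errstate(invalid="ignore", divide="ignore"):
                tval = fit.beta / se
            pv = 2.0 * t_dist.sf(np.abs(tval), fit.residual_df)
            col_of = {c: i for i, c in enumerate(keep)}
            for gi, gc in enumerate(gamma_cols):
                if gc in col_of:
                    pmat[p, gi] = pv[col_of[gc]]
                    gmat[p, gi] = fit.beta[col_of[gc]]

    with np.errstate(invalid="ignore"):
        any_ok = np.isfinite(pmat).any(axis=1)
        scores = np.where(
            any_ok, np.nanmin(np.where(np.isfinite(pmat), pmat, np.inf), axis=1), np.nan
        )
    n_missing = int((~any_ok).sum())
    if n_missing:
        logger.info("PolyReg: %d proteins without any estimable condition term", n_missing)
    return ModuleResult(
        name="PolyReg",
        scores=scores,
        p_matrix=pmat,
        extra={"gamma": gmat, "fit_kind": "random-intercept" if random_intercept else "fixed"},
    )
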