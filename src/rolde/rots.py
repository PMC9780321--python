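"""Reproducibility-optimized test statistic (ROTS).

The regularized statistic family is

* two groups:        d = |x1 - x2| / (a1 + a2 * s)
* three or more:     d = sqrt(MSB) / (a1 + a2 * sqrt(MSW))

where ``s`` is the pooled standard error of the mean difference and MSB / MSW
are the between- and within-group mean squares of a one-way ANOVA over the
observed values.  At ``alpha = (0, 1)`` the ordering coincides with the
classical |t| (two groups) or F (multigroup) ordering.

The regularization pair ``(a1, a2)`` and the top-list size ``k`` are chosen to
maximize the reproducibility Z-score of the top-k detections over
group-preserving bootstrap pairs, calibrated against group-label-permuted
bootstrap pairs.  Per-feature significance values are pooled permutation
p-values computed at the selected regularization.

Missing values never raise: they only shrink per-group observation counts.  A
feature needs at least two observed values in each of at least two groups to
receive a statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RotsSettings",
    "RotsResult",
    "default_alpha_grid",
    "default_k_grid",
    "modified_statistic",
    "optimize_reproducibility",
    "rots_pvalues",
    "rots",
]


def default_alpha_grid() -> list[tuple[float, float]]:
    """Regularizer grid: a2 = 1 with a1 spanning shrinkage-to-ordinary range,
    plus the fold-change-like point (1, 0)."""
    a1 = [0.0] + [round(0.01 * i, 2) for i in range(1, 11)] + [
        round(0.1 * i, 1) for i in range(2, 11)
    ] + [1.5, 2.0, 3.0, 5.0]
    grid: list[tuple[float, float]] = [(a, 1.0) for a in a1]
    grid.append((1.0, 0.0))
    return grid


def default_k_grid(n_valid: int, k_max: int | None = None) -> list[int]:
    """Geometric top-list-size grid from 25 up to min(k_max, n_valid / 4)."""
    cap = max(1, n_valid // 4)
    if k_max is not None:
        cap = min(cap, k_max)
    ks: list[int] = []
    k = 25
    while k <= cap:
        ks.append(k)
        k *= 2
    if not ks:
        ks = [cap]
    elif ks[-1] < cap:
        ks.append(cap)
    return ks


@dataclass
class RotsSettings:
    """Tuning knobs of the reproducibility optimization.

    b: number of bootstrap pairs (the same number of permuted-label null
    pairs is drawn).  k_max caps the top-list-size grid.  n_perm defaults to
    the smallest count giving a pooled null of at least ``min_pooled_null``
    comparisons.
    """

    b: int = 500
    alpha_grid: list[tuple[float, float]] | None = None
    k_grid: list[int] | None = None
    k_max: int | None = None
    n_perm: int | None = None
    min_pooled_null: int = 100_000


@dataclass
class RotsResult:
    statistic: np.ndarray
    p_value: np.ndarray | None
    alpha: tuple[float, float]
    top_list_size: int
    reproducibility_z: float
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# statistic
# ---------------------------------------------------------------------------

def _group_moments(values: np.ndarray, groups: np.ndarray):
    """Per-group observation counts, sums and sums of squares (NaN-aware).

    Returns arrays of shape (G, F): counts n, means m, within-group sum of
    squared deviations ss.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    F = values.shape[0]
    n = np.zeros((len(labels), F))
    m = np.full((len(labels), F), np.nan)
    ss = np.zeros((len(labels), F))
    for gi, g in enumerate(labels):
        block = values[:, groups == g]
        finite = np.isfinite(block)
        cnt = finite.sum(axis=1)
        x = np.where(finite, block, 0.0)
        s1 = x.sum(axis=1)
        s2 = (x * x).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cnt > 0, s1 / np.maximum(cnt, 1), np.nan)
            dev = s2 - np.where(cnt > 0, s1 * s1 / np.maximum(cnt, 1), 0.0)
        n[gi] = cnt
        m[gi] = mean
        ss[gi] = np.maximum(dev, 0.0)  # guard tiny negative rounding
    return labels, n, m, ss


def _numerator_scale(values: np.ndarray, groups: np.ndarray):
    """Per-feature (numerator, scale, valid) of the regularized statistic.

    Two groups at the dataset level use the t-form; otherwise the
    sqrt(MSB)/sqrt(MSW) ANOVA form.  Validity requires >= 2 observed values
    in each of >= 2 groups.
    """
    labels, n, m, ss = _group_moments(values, groups)
    G = len(labels)
    valid = (n >= 2).sum(axis=0) >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        if G == 2:
            n1, n2 = n[0], n[1]
            num = np.abs(m[0] - m[1])
            df = n1 + n2 - 2
            sp2 = (ss[0] + ss[1]) / np.where(df > 0, df, np.nan)
            scale = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        else:
            present = n >= 1
            g_eff = present.sum(axis=0)
            ntot = n.sum(axis=0)
            with np.errstate(invalid="ignore"):
                grand = np.nansum(np.where(present, n * m, 0.0), axis=0) / np.maximum(ntot, 1)
                ssb = np.nansum(np.where(present, n * (m - grand) ** 2, 0.0), axis=0)
            df_b = g_eff - 1
            df_w = ntot - g_eff
            msb = ssb / np.where(df_b > 0, df_b, np.nan)
            msw = ss.sum(axis=0) / np.where(df_w > 0, df_w, np.nan)
            num = np.sqrt(np.maximum(msb, 0.0))
            scale = np.sqrt(np.maximum(msw, 0.0))
            valid = valid & (df_w > 0) & (df_b > 0)
    num = np.where(valid, num, np.nan)
    scale = np.where(valid, scale, np.nan)
    return num, scale, valid


def _statistic_from(num: np.ndarray, scale: np.ndarray, alpha: tuple[float, float]) -> np.ndarray:
    a1, a2 = alpha
    denom = a1 + a2 * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / denom
    bad = ~np.isfinite(d)
    if a1 == 0 and np.any(bad & np.isfinite(num)):
        logger.debug("zero denominator with a1 = 0 for %d features", int(np.sum(bad & np.isfinite(num))))
    return np.where(bad, np.nan, d)


def modified_statistic(
    values: np.ndarray, groups: np.ndarray, alpha: tuple[float, float]
) -> np.ndarray:
    """Regularized t / sqrt(F) statistic per feature; NaN for invalid features."""
    a1, a2 = alpha
    if a1 < 0 or a2 < 0 or (a1 == 0 and a2 == 0):
        raise ValueError("alpha components must be >= 0 and not both zero")
    if len(np.unique(np.asarray(groups))) < 2:
        raise ValueError("need at least 2 groups")
    num, scale, _ = _numerator_scale(values, groups)
    return _statistic_from(num, scale, alpha)


# ---------------------------------------------------------------------------
# reproducibility optimization
# ---------------------------------------------------------------------------

def _ranks_desc(d: np.ndarray) -> np.ndarray:
    """0-based rank by descending statistic, NaN last, ties by feature index."""
    key = np.where(np.isfinite(d), -d, np.inf)
    order = np.argsort(key, kind="stable")
    ranks = np.empty(len(d), dtype=np.int64)
    ranks[order] = np.arange(len(d))
    return ranks


def _overlap_counts(r1: np.ndarray, r2: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Proportional top-k overlap of two rank vectors for each k in ks."""
    m = np.maximum(r1, r2)
    counts = np.bincount(m, minlength=len(r1)).cumsum()
    return counts[ks - 1] / ks


def _bootstrap_indices(rng: np.random.Generator, group_cols: list[np.ndarray]) -> np.ndarray:
    parts = [cols[rng.integers(0, len(cols), size=len(cols))] for cols in group_cols]
    return np.concatenate(parts)


def optimize_reproducibility(
    values: np.ndarray,
    groups: np.ndarray,
    settings: RotsSettings | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> RotsResult:
    """Select (alpha, k) maximizing the bootstrap reproducibility Z-score.

    For every candidate alpha and top-list size k the mean proportional
    overlap R_k of top-k lists over ``b`` group-preserving bootstrap pairs is
    compared with its null counterpart R0_k from group-label-permuted
    bootstrap pairs: Z_k = (R_k - R0_k) / sd(R0_k).  The statistic of the
    winning alpha on the original data is returned.
    """
    settings = settings or RotsSettings()
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if settings.b < 2:
        raise ValueError("need at least 2 bootstrap pairs")

    num0, scale0, valid = _numerator_scale(values, groups)
    n_valid = int(valid.sum())
    alpha_grid = settings.alpha_grid or default_alpha_grid()
    ks = np.asarray(
        settings.k_grid if settings.k_grid is not None else default_k_grid(n_valid, settings.k_max),
        dtype=np.int64,
    )
    if n_valid < ks.min():
        raise ValueError(
            f"insufficient features: {n_valid} valid features < smallest top-list size {ks.min()}"
        )

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    boot_ss, null_ss = ss.spawn(2)
    rng_b = np.random.default_rng(boot_ss)
    rng_0 = np.random.default_rng(null_ss)

    labels = np.unique(groups)
    group_cols = [np.flatnonzero(groups == g) for g in labels]
    sorted_cols = np.concatenate(group_cols)
    sorted_groups = groups[sorted_cols]

    n_alpha, n_k, B = len(alpha_grid), len(ks), settings.b
    R = np.zeros((n_alpha, n_k))
    R0 = np.zeros((B, n_alpha, n_k))

    def pair_overlaps(vals_a: np.ndarray, vals_b: np.ndarray) -> np.ndarray:
        na, sa, _ = _numerator_scale(vals_a, sorted_groups)
        nb, sb, _ = _numerator_scale(vals_b, sorted_groups)
        out = np.empty((n_alpha, n_k))
        for ai, alpha in enumerate(alpha_grid):
            ra = _ranks_desc(_statistic_from(na, sa, alpha))
            rb = _ranks_desc(_statistic_from(nb, sb, alpha))
            out[ai] = _overlap_counts(ra, rb, ks)
        return out

    for b in range(B):
        ia = _bootstrap_indices(rng_b, group_cols)
        ib = _bootstrap_indices(rng_b, group_cols)
        R += pair_overlaps(values[:, ia], values[:, ib])

        # permuted labels: columns reassigned to groups of the original sizes
        flat = sorted_cols[rng_0.permutation(len(sorted_cols))]
        start, pcols = 0, []
        for cols in group_cols:
            pcols.append(flat[start : start + len(cols)])
            start += len(cols)
        ia0 = _bootstrap_indices(rng_0, pcols)
        ib0 = _bootstrap_indices(rng_0, pcols)
        R0[b] = pair_overlaps(values[:, ia0], values[:, ib0])

    R /= B
    R0_mean = R0.mean(axis=0)
    R0_sd = R0.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (R - R0_mean) / R0_sd
    Z = np.where(np.isfinite(Z), Z, -np.inf)

    if len(alpha_grid) == 1 and n_k == 1:
        ai, ki = 0, 0
    else:
        ai, ki = np.unravel_index(int(np.argmax(Z)), Z.shape)
    alpha = tuple(alpha_grid[ai])
    stat = _statistic_from(num0, scale0, alpha)
    return RotsResult(
        statistic=stat,
        p_value=None,
        alpha=alpha,
        top_list_size=int(ks[ki]),
        reproducibility_z=float(Z[ai, ki]),
        extra={"Z": Z, "alpha_grid": alpha_grid, "k_grid": ks},
    )


# ---------------------------------------------------------------------------
# permutation p-values
# ---------------------------------------------------------------------------

def rots_pvalues(
    observed: np.ndarray,
    values: np.ndarray,
    groups: np.ndarray,
    alpha: tuple[float, float],
    n_perm: int | None = None,
    min_pooled_null: int = 100_000,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Pooled permutation p-values for the regularized statistic.

    Null statistics from ``n_perm`` group-label permutations are pooled over
    all valid features; p = (1 + #{null >= observed}) / (1 + #null).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    observed = np.asarray(observed, dtype=float)
    n_valid = int(np.isfinite(observed).sum())
    if n_perm is None:
        n_perm = max(1, math.ceil(min_pooled_null / max(n_valid, 1)))
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    pooled: list[np.ndarray] = []
    for _ in range(n_perm):
        perm = rng.permutation(len(groups))
        d = modified_statistic(values, groups[perm], alpha)
        pooled.append(d[np.isfinite(d)])
    null = np.sort(np.concatenate(pooled)) if pooled else np.array([])
    n_null = len(null)
    p = np.full(len(observed), np.nan)
    ok = np.isfinite(observed)
    if n_null:
        ge = n_null - np.searchsorted(null, observed[ok], side="left")
        p[ok] = (1.0 + ge) / (1.0 + n_null)
    else:
        p[ok] = 1.0
    return p


def rots(
    values: np.ndarray,
    groups: np.ndarray,
    settings: RotsSettings | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> RotsResult:
    """Full ROTS: reproducibility optimization followed by permutation p-values."""
    settings = settings or RotsSettings()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    opt_ss, perm_ss = ss.spawn(2)
    res = optimize_reproducibility(values, groups, settings, seed=opt_ss)
    res.p_value = rots_pvalues(
        res.statistic,
        values,
        groups,
        res.alpha,
        n_perm=settings.n_perm,
        min_pooled_null=settings.min_pooled_null,
        seed=perm_ss,
    )
    return res
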