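"""Combining the module scores into the final RolDE result.

Module scores (smaller = stronger evidence) are converted to ascending ranks
with average tie-ranks; a protein missing a module's score receives the worst
rank N for that module, so every protein always obtains a final score.  The
overall score is the rank product

    S_RolDE = cbrt( r(S_RegROTS) * r(S_DiffROTS) * r(S_PolyReg) )

Its significance is estimated by simulation: under the null the significance
values inside a RegROTS/DiffROTS run (and the condition-coefficient p-values
of PolyReg) are approximately uniform, so simulated counterparts are drawn
from U(0,1), ordered to retain the experimental protein ordering (which
preserves between-run dependencies), mapped to the rank of the nearest
experimental significance value (rank-product modules), combined exactly as
the experimental pipeline, and compared against the experimental rank
products.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix, ModuleResult, StudyDesign
from .rots import RotsSettings, rots

__all__ = [
    "module_ranks",
    "rolde_rank_product",
    "simulate_null_rank_products",
    "estimate_significance",
    "adjust_pvalues",
    "baseline_rots",
]


def module_ranks(scores: np.ndarray) -> np.ndarray:
    """Ascending average-tie ranks; missing scores get the worst rank N."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    ranks = np.full(n, float(n))
    ok = np.isfinite(scores)
    if ok.any():
        ranks[ok] = rankdata(scores[ok], method="average")
    return ranks


def rolde_rank_product(ranks: np.ndarray) -> np.ndarray:
    """Geometric mean over the module ranks (rows: proteins, cols: modules)."""
    ranks = np.asarray(ranks, dtype=float)
    return np.exp(np.log(ranks).mean(axis=1))


def _rank_rows(scores: np.ndarray, n: int) -> np.ndarray:
    """Row-wise module ranking of simulated scores; NaN -> worst rank n."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = rankdata(scores, method="average", axis=1, nan_policy="omit")
    return np.where(np.isnan(r), float(n), r)


def _simulate_rank_product_module(
    pmat: np.ndarray, rounds: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulated internal rank products for a RegROTS/DiffROTS-style module.

    Per run: draw as many uniforms as there are valid experimental p-values,
    order them to retain the experimental protein ordering, replace each with
    the rank of the nearest experimental p-value (ties toward the smaller
    rank), and combine across runs with the geometric mean.
    """
    P, R = pmat.shape
    log_sum = np.zeros((rounds, P))
    count = np.zeros(P)
    for r in range(R):
        valid = np.flatnonzero(np.isfinite(pmat[:, r]))
        nv = len(valid)
        if nv == 0:
            continue
        order = valid[np.argsort(pmat[valid, r], kind="stable")]
        q = pmat[order, r]
        rk_sorted = rankdata(q, method="average")
        mids = (q[:-1] + q[1:]) / 2.0
        u = rng.random((rounds, nv))
        u.sort(axis=1)
        j = np.searchsorted(mids, u.ravel(), side="left").reshape(rounds, nv)
        sim_rank = rk_sorted[j]
        log_sum[:, order] += np.log(sim_rank)
        count[order] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        sim_score = np.exp(log_sum / np.maximum(count, 1))
    sim_score[:, count == 0] = np.nan
    return sim_score


def _simulate_min_p_module(
    pmat: np.ndarray, rounds: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulated representative significance values for a min-p module."""
    P, K = pmat.shape
    flat = pmat.ravel()
    valid = np.flatnonzero(np.isfinite(flat))
    if len(valid) == 0:
        return np.full((rounds, P), np.nan)
    order = np.argsort(flat[valid], kind="stable")
    u = rng.random((rounds, len(valid)))
    u.sort(axis=1)
    placed = np.empty_like(u)
    placed[:, order] = u
    sim_flat = np.full((rounds, P * K), np.nan)
    sim_flat[:, valid] = placed
    sim = sim_flat.reshape(rounds, P, K)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.nanmin(sim, axis=2)


def simulate_null_rank_products(
    modules: list[ModuleResult],
    n_proteins: int,
    n_sim: int = 500_000,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Pool of simulated null rank products (length >= n_sim)."""
    if n_sim < 10_000:
        warnings.warn("n_sim < 10^4 gives unstable tail estimates", stacklevel=2)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    rounds = max(1, int(np.ceil(n_sim / n_proteins)))

    module_rank_sims = []
    for mod in modules:
        if mod.kind == "rank_product":
            sim_score = _simulate_rank_product_module(mod.run_pvalues, rounds, rng)
        else:
            sim_score = _simulate_min_p_module(mod.p_matrix, rounds, rng)
        module_rank_sims.append(_rank_rows(sim_score, n_proteins))

    log_s = np.zeros_like(module_rank_sims[0])
    for r in module_rank_sims:
        log_s += np.log(r)
    return np.exp(log_s / len(module_rank_sims)).ravel()


def estimate_significance(s_rolde: np.ndarray, simulated: np.ndarray) -> np.ndarray:
    """Fraction of simulated rank products <= each experimental rank product,
    floored at 1 / #simulated."""
    simulated = np.sort(np.asarray(simulated, dtype=float))
    n = len(simulated)
    if n == 0:
        raise ValueError("empty simulated distribution")
    le = np.searchsorted(simulated, np.asarray(s_rolde, dtype=float), side="right")
    return np.maximum(le / n, 1.0 / n)


def adjust_pvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (default) or Bonferroni adjustment, clipped to (0, 1]."""
    p = np.asarray(p, dtype=float)
    key = {"bh": "fdr_bh", "fdr": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method: {method!r}")
    adj = multipletests(p, method=key)[1]
    return np.clip(adj, 1e-300, 1.0)


def baseline_rots(
    expr: ExpressionMatrix,
    design: StudyDesign,
    settings: RotsSettings | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> ModuleResult:
    """Cross-sectional baseline: two-group ROTS per timepoint, min p over
    timepoints as the representative significance value."""
    expr.check_samples(design)
    if not design.aligned:
        raise ValueError("baseline ROTS requires aligned time points")
    values = expr.values
    col_index = {s: i for i, s in enumerate(expr.samples)}
    c1, _ = design.conditions
    grid = design.timepoints
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(len(grid))
    settings = settings or RotsSettings()

    P = values.shape[0]
    pmat = np.full((P, len(grid)), np.nan)
    for ti, tp in enumerate(grid):
        rows = design.table[design.table["timepoint"] == tp]
        cols = [col_index[s] for s in rows["sample_id"]]
        groups = (rows["condition"] != c1).astype(int).to_numpy()
        res = rots(values[:, cols], groups, settings, seed=seeds[ti])
        pmat[:, ti] = res.p_value

    any_ok = np.isfinite(pmat).any(axis=1)
    with np.errstate(invalid="ignore"):
        scores = np.where(
            any_ok, np.nanmin(np.where(np.isfinite(pmat), pmat, np.inf), axis=1), np.nan
        )
    return ModuleResult(name="BaselineROTS", scores=scores, p_matrix=pmat)
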