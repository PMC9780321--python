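"""DiffROTS: direct cross-condition expression-difference testing.

Aligned studies: for every cross-condition individual pair (u, v) the
per-timepoint differences dy_tuv = y_tu - y_tv are formed (missing whenever
either measurement is missing), pairs are organized into the same runs as
RegROTS, and multigroup ROTS tests the null "dy_1 = ... = dy_T = 0" per run
(with the same zero-anchor convention).  The module score is the rank product
of the protein's run ranks.

Non-aligned studies: per-timepoint comparison is impossible, so the module
instead removes time-associated trends of increasing complexity and compares
what remains.  For each degree j = 0..d a model
y = b0 + b_j t^j + delta_0u + eps with a random individual baseline is fitted
per protein; the marginal residuals of the two conditions are compared with
two-group ROTS and the score is the minimum significance value over degrees.
"""

from __future__ import annotations

import logging

import numpy as np

from .data import ExpressionMatrix, ModuleResult, StudyDesign
from .mixed import fit_random_intercept
from .regrots import pair_runs, score_runs
from .rots import RotsSettings, rots

logger = logging.getLogger(__name__)

__all__ = ["diffrots_score_aligned", "diffrots_score_nonaligned", "diffrots_score"]


def diffrots_score_aligned(
    expr: ExpressionMatrix,
    design: StudyDesign,
    settings: RotsSettings | None = None,
    anchor: bool = True,
    seed: int | np.random.SeedSequence | None = None,
) -> ModuleResult:
    """Per-protein DiffROTS score for a common time grid (smaller = stronger)."""
    expr.check_samples(design)
    values = expr.values
    col_index = {s: i for i, s in enumerate(expr.samples)}
    c1, c2 = design.conditions
    runs = pair_runs(design.individuals(c1), design.individuals(c2))
    grid = design.timepoints
    P = values.shape[0]

    def sample_col(ind: str, tp: float) -> np.ndarray:
        sid = design.sample_of(ind, tp)
        if sid is None:
            return np.full(P, np.nan)
        return values[:, col_index[sid]]

    matrices, groups = [], []
    for run in runs:
        blocks, labels = [], []
        for ti, tp in enumerate(grid):
            for (u, v) in run:
                blocks.append(sample_col(u, tp) - sample_col(v, tp))
                labels.append(ti)
        if anchor:
            for (u, v) in run:
                pair_ok = np.zeros(P, dtype=bool)
                for tp in grid:
                    pair_ok |= np.isfinite(sample_col(u, tp) - sample_col(v, tp))
                blocks.append(np.where(pair_ok, 0.0, np.nan))
                labels.append(len(grid))
        matrices.append(np.column_stack(blocks))
        groups.append(np.asarray(labels))
    return score_runs(matrices, groups, settings, seed, name="DiffROTS")


def nonaligned_degree(median_timepoints: float) -> int:
    """Maximum trend degree for the residual comparison: max{2, min(m-1, 5)}."""
    m = float(median_timepoints)
    if m < 2:
        raise ValueError("too few time points: median timepoint count must be >= 2")
    return max(2, min(int(m) - 1, 5))


def diffrots_score_nonaligned(
    expr: ExpressionMatrix,
    design: StudyDesign,
    degree: int | None = None,
    settings: RotsSettings | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> ModuleResult:
    """Per-protein DiffROTS score for non-aligned time grids.

    S = min(p_0, ..., p_d) over the per-degree residual comparisons.
    """
    expr.check_samples(design)
    if degree is None:
        degree = nonaligned_degree(design.median_timepoints)
    values = expr.values
    P, _ = values.shape
    sample_ids = expr.samples
    table = design.table.set_index("sample_id").loc[sample_ids]
    t = table["timepoint"].to_numpy(dtype=float)
    ind = table["individual"].to_numpy()
    cond = table["condition"].to_numpy()
    c1, _ = design.conditions
    cond_groups = (cond != c1).astype(int)
    # time standardized before powering to keep high-degree regressors tame
    ts = (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(degree + 1)
    settings = settings or RotsSettings()

    pmat = np.full((P, degree + 1), np.nan)
    for j in range(degree + 1):
        X_full = (
            np.ones((len(t), 1))
            if j == 0
            else np.column_stack([np.ones(len(t)), ts**j])
        )
        residuals = np.full((P, len(t)), np.nan)
        n_degenerate = 0
        for p in range(P):
            obs = np.isfinite(values[p])
            if obs.sum() < X_full.shape[1] + 2:
                n_degenerate += 1
                continue
            fit = fit_random_intercept(values[p, obs], X_full[obs], ind[obs])
            if fit is None:
                n_degenerate += 1
                continue
            residuals[p, obs] = values[p, obs] - fit.fitted
        if n_degenerate:
            logger.debug("degree %d: %d degenerate fits skipped", j, n_degenerate)
        if np.isfinite(residuals).sum() == 0:
            continue
        res = rots(residuals, cond_groups, settings, seed=seeds[j])
        pmat[:, j] = res.p_value

    with np.errstate(invalid="ignore"):
        any_ok = np.isfinite(pmat).any(axis=1)
        scores = np.where(any_ok, np.nanmin(np.where(np.isfinite(pmat), pmat, np.inf), axis=1), np.nan)
    return ModuleResult(name="DiffROTS", scores=scores, p_matrix=pmat)


def diffrots_score(
    expr: ExpressionMatrix,
    design: StudyDesign,
    settings: RotsSettings | None = None,
    anchor: bool = True,
    seed: int | np.random.SeedSequence | None = None,
) -> ModuleResult:
    """Dispatch on the study's alignment flag."""
    if design.aligned:
        return diffrots_score_aligned(expr, design, settings, anchor, seed)
    return diffrots_score_nonaligned(expr, design, settings=settings, seed=seed)
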