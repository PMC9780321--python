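"""RegROTS: per-individual trend regression combined with multigroup ROTS.

Each protein's trajectory is fitted per individual with an orthogonal
polynomial of degree d = max{1, min(floor(m/2), 4)}, m being the median number
of timepoints over individuals.  Coefficients of equal degree are differenced
across all cross-condition individual pairs; the pairs are organized into runs
(a cyclic Latin-square pairing in which each individual appears at most once
per run).  Within a run, multigroup ROTS tests whether any coefficient
difference departs from zero; proteins are ranked by the run's significance
values and the RegROTS score is the geometric mean of a protein's ranks over
its valid runs (rank product).

The tested null is "all coefficient differences equal zero".  Because a plain
equality-of-group-means ANOVA cannot see a shift common to *all* degrees, a
pseudo-group of zeros (one per pair) is anchored to the comparison by default,
making the stated null the literally tested one.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .data import ExpressionMatrix, ModuleResult, StudyDesign
from .rots import RotsSettings, rots

__all__ = [
    "regrots_degree",
    "orthogonal_basis",
    "fit_individual_models",
    "pair_runs",
    "regrots_score",
    "score_runs",
]


def regrots_degree(median_timepoints: float) -> int:
    """Per-individual polynomial degree: max{1, min(floor(m/2), 4)}."""
    m = float(median_timepoints)
    if m < 2:
        raise ValueError("too few time points: median timepoint count must be >= 2")
    return max(1, min(int(m // 2), 4))


def orthogonal_basis(
    timepoints: np.ndarray, degree: int, scale: bool = True
) -> np.ndarray:
    """Discrete orthogonal polynomial basis (degrees 1..degree) on a time grid.

    Built by the classical three-term recursion
    ``p_{j+1}(t) = (t - a_j) p_j(t) - b_j p_{j-1}(t)``; columns are mutually
    orthogonal and orthogonal to the constant.  With ``scale`` the columns are
    normalized to unit L2 norm; without it the raw recursion output is kept so
    that coefficients stay comparable across individuals measured on
    different time grids.
    """
    t = np.asarray(timepoints, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if len(np.unique(t)) <= degree:
        raise ValueError(
            f"degree too high: degree {degree} needs > {degree} distinct timepoints"
        )
    cols = []
    p_prev = np.zeros(len(t))
    p_cur = np.ones(len(t))
    for j in range(degree):
        a = (t * p_cur * p_cur).sum() / (p_cur * p_cur).sum()
        if j == 0:
            p_next = (t - a) * p_cur
        else:
            b = (p_cur * p_cur).sum() / (p_prev * p_prev).sum()
            p_next = (t - a) * p_cur - b * p_prev
        cols.append(p_next)
        p_prev, p_cur = p_cur, p_next
    basis = np.column_stack(cols)
    if scale:
        basis = basis / np.linalg.norm(basis, axis=0)
    return basis


def fit_individual_models(
    expr: ExpressionMatrix,
    design: StudyDesign,
    degree: int,
) -> tuple[np.ndarray, list[str]]:
    """Least-squares orthogonal-polynomial fit per (protein, individual).

    Returns ``(coef, individuals)`` where ``coef`` has shape
    (n_proteins, n_individuals, degree + 1) with the intercept first; NaN rows
    mark invalid (underdetermined) fits.  An individual's fit is valid iff it
    has at least degree + 1 observed values at distinct timepoints.

    Aligned studies share one unit-norm basis built on the union time grid;
    non-aligned studies use per-individual unscaled bases.
    """
    values = expr.values
    P = values.shape[0]
    c1, c2 = design.conditions
    individuals = design.individuals(c1) + design.individuals(c2)
    coef = np.full((P, len(individuals), degree + 1), np.nan)

    col_index = {s: i for i, s in enumerate(expr.samples)}
    if design.aligned:
        grid = design.timepoints
        basis_grid = orthogonal_basis(grid, degree, scale=True)
        grid_pos = {tp: i for i, tp in enumerate(grid)}

    for ui, ind in enumerate(individuals):
        rows = design.samples_of(ind)
        tps = rows["timepoint"].to_numpy()
        sample_cols = [col_index[s] for s in rows["sample_id"]]
        if design.aligned:
            basis = basis_grid[[grid_pos[tp] for tp in tps], :]
        else:
            if len(np.unique(tps)) <= degree:
                continue  # cannot support the common degree: all fits invalid
            basis = orthogonal_basis(tps, degree, scale=False)
        X_full = np.column_stack([np.ones(len(tps)), basis])
        Y = values[:, sample_cols]
        obs = np.isfinite(Y)

        patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
        for pi, pat in enumerate(patterns):
            if pat.sum() < degree + 1:
                continue
            sel = np.flatnonzero(inverse == pi)
            X = X_full[pat, :]
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            beta = np.linalg.pinv(X) @ Y[np.ix_(sel, np.flatnonzero(pat))].T
            coef[sel, ui, :] = beta.T
    return coef, individuals


def pair_runs(ids_c1: list, ids_c2: list) -> list[list[tuple]]:
    """Cyclic Latin-square pairing of individuals across conditions.

    With n individuals per condition, returns exactly n runs jointly covering
    all n^2 (u, v) pairs, each individual appearing once per run.  With
    unequal sizes there are max(n1, n2) runs of min(n1, n2) pairs; every
    distinct pair occurs exactly once and each individual appears at most
    once per run on either side.
    """
    if not ids_c1 or not ids_c2:
        raise ValueError("both conditions must be nonempty")
    if len(ids_c1) <= len(ids_c2):
        a, b, flip = list(ids_c1), list(ids_c2), False
    else:
        a, b, flip = list(ids_c2), list(ids_c1), True
    runs = []
    for r in range(len(b)):
        run = []
        for i in range(len(a)):
            u, v = a[i], b[(i + r) % len(b)]
            run.append((v, u) if flip else (u, v))
        runs.append(run)
    return runs


def score_runs(
    run_matrices: list[np.ndarray],
    run_groups: list[np.ndarray],
    settings: RotsSettings | None = None,
    seed: int | np.random.SeedSequence | None = None,
    name: str = "module",
) -> ModuleResult:
    """Run multigroup ROTS per run, rank proteins by run p-value, and combine
    ranks with the rank product (geometric mean over a protein's valid runs)."""
    settings = settings or RotsSettings()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(len(run_matrices))
    P = run_matrices[0].shape[0]
    pmat = np.full((P, len(run_matrices)), np.nan)
    for r, (mat, grp) in enumerate(zip(run_matrices, run_groups)):
        res = rots(mat, grp, settings, seed=seeds[r])
        pmat[:, r] = res.p_value

    log_ranks = np.zeros(P)
    n_ranks = np.zeros(P)
    ranks = np.full((P, pmat.shape[1]), np.nan)
    for r in range(pmat.shape[1]):
        ok = np.isfinite(pmat[:, r])
        if ok.sum() == 0:
            continue
        rk = rankdata(pmat[ok, r], method="average")
        ranks[ok, r] = rk
        log_ranks[ok] += np.log(rk)
        n_ranks[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(n_ranks > 0, np.exp(log_ranks / np.maximum(n_ranks, 1)), np.nan)
    return ModuleResult(
        name=name, scores=scores, run_pvalues=pmat, extra={"run_ranks": ranks}
    )


def regrots_score(
    expr: ExpressionMatrix,
    design: StudyDesign,
    degree: int | None = None,
    settings: RotsSettings | None = None,
    anchor: bool = True,
    seed: int | np.random.SeedSequence | None = None,
) -> ModuleResult:
    """Per-protein RegROTS score (smaller = stronger evidence)."""
    expr.check_samples(design)
    if degree is None:
        degree = regrots_degree(design.median_timepoints)
    coef, individuals = fit_individual_models(expr, design, degree)
    idx = {u: i for i, u in enumerate(individuals)}
    c1, c2 = design.conditions
    runs = pair_runs(design.individuals(c1), design.individuals(c2))

    matrices, groups = [], []
    for run in runs:
        blocks, labels = [], []
        for j in range(degree + 1):
            for (u, v) in run:
                blocks.append(coef[:, idx[u], j] - coef[:, idx[v], j])
                labels.append(j)
        if anchor:
            # zero pseudo-observations: one per pair, NaN where the pair is invalid
            for (u, v) in run:
                pair_ok = np.isfinite(coef[:, idx[u], 0]) & np.isfinite(coef[:, idx[v], 0])
                blocks.append(np.where(pair_ok, 0.0, np.nan))
                labels.append(degree + 1)
        matrices.append(np.column_stack(blocks))
        groups.append(np.asarray(labels))
    return score_runs(matrices, groups, settings, seed, name="RegROTS")
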