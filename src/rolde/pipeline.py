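"""End-to-end RolDE pipeline: modules -> ranks -> rank product -> significance."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combine import (
    adjust_pvalues,
    estimate_significance,
    module_ranks,
    rolde_rank_product,
    simulate_null_rank_products,
)
from .data import ExpressionMatrix, ModuleResult, StudyDesign
from .diffrots import diffrots_score
from .polyreg import polyreg_score
from .regrots import regrots_score
from .rots import RotsSettings

logger = logging.getLogger(__name__)

__all__ = ["RoldeResult", "run_rolde"]


@dataclass
class RoldeResult:
    """Final per-protein table plus the module internals."""

    table: pd.DataFrame
    modules: list[ModuleResult] = field(default_factory=list)
    simulated: np.ndarray | None = None

    def detections(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["adjusted_p"] <= alpha]


def run_rolde(
    expr: ExpressionMatrix,
    design: StudyDesign,
    settings: RotsSettings | None = None,
    n_sim: int = 500_000,
    fdr_method: str = "bh",
    anchor: bool = True,
    seed: int | np.random.SeedSequence | None = None,
) -> RoldeResult:
    """Run RegROTS, DiffROTS and PolyReg, combine them by rank product and
    estimate significance by null simulation.

    Every protein in the input receives a final score and rank: a module that
    could not score a protein contributes the worst rank N.
    """
    expr.check_samples(design)
    settings = settings or RotsSettings()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    reg_ss, diff_ss, sim_ss = ss.spawn(3)

    logger.info("RegROTS (aligned=%s)", design.aligned)
    reg = regrots_score(expr, design, settings=settings, anchor=anchor, seed=reg_ss)
    logger.info("DiffROTS")
    diff = diffrots_score(expr, design, settings=settings, anchor=anchor, seed=diff_ss)
    logger.info("PolyReg")
    poly = polyreg_score(expr, design)
    modules = [reg, diff, poly]

    n = len(expr.proteins)
    for mod in modules:
        n_valid = int(np.isfinite(mod.scores).sum())
        logger.info("%s: %d/%d proteins with valid scores (%.1f%%)",
                    mod.name, n_valid, n, 100.0 * n_valid / max(n, 1))

    ranks = np.column_stack([module_ranks(m.scores) for m in modules])
    s_rolde = rolde_rank_product(ranks)
    simulated = simulate_null_rank_products(modules, n, n_sim=n_sim, seed=sim_ss)
    est_p = estimate_significance(s_rolde, simulated)
    adj_p = adjust_pvalues(est_p, method=fdr_method)

    table = pd.DataFrame(
        {
            "protein_id": expr.proteins,
            "S_RegROTS": reg.scores,
            "S_DiffROTS": diff.scores,
            "S_PolyReg": poly.scores,
            "rank_RegROTS": ranks[:, 0],
            "rank_DiffROTS": ranks[:, 1],
            "rank_PolyReg": ranks[:, 2],
            "S_RolDE": s_rolde,
            "estimated_p": est_p,
            "adjusted_p": adj_p,
            "used_RegROTS": np.isfinite(reg.scores),
            "used_DiffROTS": np.isfinite(diff.scores),
            "used_PolyReg": np.isfinite(poly.scores),
        }
    ).set_index("protein_id")
    return RoldeResult(table=table, modules=modules, simulated=simulated)
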