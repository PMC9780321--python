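"""Core data containers: expression matrices, study designs, module results.

The package operates on a log-scale protein x sample intensity matrix together
with a design table that maps every sample to a condition (exactly two), an
individual and a timepoint.  A study is *aligned* when all individuals are
measured on the same time grid; several modules switch behaviour on this flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("sample_id", "condition", "individual", "timepoint")


@dataclass(frozen=True)
class StudyDesign:
    """Per-sample annotation for a two-condition longitudinal study.

    Parameters
    ----------
    table:
        DataFrame with columns ``sample_id``, ``condition``, ``individual``,
        ``timepoint``.  Each individual belongs to exactly one condition and
        has at least two distinct timepoints; (individual, timepoint) pairs
        are unique.
    aligned:
        Whether all individuals share a common time grid.  Inferred from the
        table when not given.
    """

    table: pd.DataFrame
    aligned: bool

    @classmethod
    def from_frame(cls, table: pd.DataFrame, aligned: bool | None = None) -> "StudyDesign":
        missing = [c for c in DESIGN_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        table = table.loc[:, list(DESIGN_COLUMNS)].copy()
        table["timepoint"] = table["timepoint"].astype(float)
        table["sample_id"] = table["sample_id"].astype(str)
        table["individual"] = table["individual"].astype(str)
        table["condition"] = table["condition"].astype(str)

        if table["sample_id"].duplicated().any():
            dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        conditions = sorted(table["condition"].unique())
        if len(conditions) != 2:
            raise ValueError(
                f"two-condition method: found {len(conditions)} condition labels {conditions}"
            )
        conds_per_ind = table.groupby("individual")["condition"].nunique()
        bad = conds_per_ind[conds_per_ind > 1]
        if len(bad):
            raise ValueError(f"individual {bad.index[0]!r} appears in both conditions")
        if table.duplicated(subset=["individual", "timepoint"]).any():
            row = table[table.duplicated(subset=["individual", "timepoint"])].iloc[0]
            raise ValueError(
                f"duplicate timepoint {row['timepoint']} for individual {row['individual']!r}"
            )
        tps_per_ind = table.groupby("individual")["timepoint"].nunique()
        if (tps_per_ind < 2).any():
            ind = tps_per_ind[tps_per_ind < 2].index[0]
            raise ValueError(f"individual {ind!r} has fewer than 2 distinct timepoints")

        if aligned is None:
            grids = table.groupby("individual")["timepoint"].apply(lambda s: tuple(sorted(s)))
            aligned = grids.nunique() == 1
        return cls(table=table.reset_index(drop=True), aligned=bool(aligned))

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def conditions(self) -> tuple[str, str]:
        c = sorted(self.table["condition"].unique())
        return c[0], c[1]

    def individuals(self, condition: str | None = None) -> list[str]:
        t = self.table
        if condition is not None:
            t = t[t["condition"] == condition]
        # keep first-appearance order for deterministic run pairing
        return list(dict.fromkeys(t["individual"]))

    @property
    def timepoints(self) -> np.ndarray:
        """Sorted union of all timepoints in the study."""
        return np.array(sorted(self.table["timepoint"].unique()))

    @property
    def median_timepoints(self) -> float:
        """Median number of distinct timepoints over individuals (m)."""
        return float(self.table.groupby("individual")["timepoint"].nunique().median())

    def sample_of(self, individual: str, timepoint: float) -> str | None:
        t = self.table
        hit = t[(t["individual"] == individual) & (t["timepoint"] == timepoint)]
        return None if hit.empty else str(hit["sample_id"].iloc[0])

    def samples_of(self, individual: str) -> pd.DataFrame:
        t = self.table[self.table["individual"] == individual]
        return t.sort_values("timepoint")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Proteins x samples log-intensity matrix; NaN marks missing values."""

    frame: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        if frame.index.duplicated().any():
            dup = frame.index[frame.index.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")
        return cls(frame=frame.astype(float))

    @property
    def proteins(self) -> list[str]:
        return list(self.frame.index.astype(str))

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns.astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def check_samples(self, design: StudyDesign) -> None:
        mat, des = set(self.samples), set(design.sample_ids)
        if mat != des:
            extra = sorted(mat - des)
            missing = sorted(des - mat)
            raise ValueError(
                f"sample mismatch between matrix and design: "
                f"only in matrix {extra}, only in design {missing}"
            )


@dataclass
class ModuleResult:
    """Per-protein score of one RolDE module plus the internals the
    significance simulation needs.

    ``scores`` is NaN for proteins the module could not score.  Exactly one of
    ``run_pvalues`` (rank-product modules: protein x run significance values)
    or ``p_matrix`` (min-p modules: protein x component significance values)
    is set.
    """

    name: str
    scores: np.ndarray
    run_pvalues: np.ndarray | None = None
    p_matrix: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def kind(self) -> str:
        return "rank_product" if self.run_pvalues is not None else "min_p"
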