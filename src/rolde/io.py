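"""Readers and writers for the TSV interchange formats.

Expression tables: first column protein id, remaining columns sample ids,
empty cells or "NA" for missing values.  Design tables: sample_id, condition,
individual, timepoint.  All outputs are tab-separated UTF-8 with a header row
and "NA" for missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DESIGN_COLUMNS, ExpressionMatrix, StudyDesign
from .simulate import SimulatedDataset

__all__ = [
    "read_expression",
    "read_design",
    "write_expression",
    "write_design",
    "write_dataset",
    "read_dataset",
    "write_result",
    "write_manifest",
]

_NA = ["", "NA", "NaN", "nan"]


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, na_values=_NA, keep_default_na=False)


def read_expression(path: str | Path, design: StudyDesign | None = None) -> ExpressionMatrix:
    """Read a protein x sample intensity table; optionally validate that the
    sample columns match a design exactly."""
    raw = _read_table(path)
    raw = raw.set_index(raw.columns[0])
    raw.index = raw.index.astype(str)
    for col in raw.columns:
        bad = raw[col].apply(lambda v: isinstance(v, str))
        if bad.any():
            row = raw.index[bad][0]
            raise ValueError(
                f"non-numeric cell at protein {row!r}, sample {col!r}: {raw.loc[row, col]!r}"
            )
    expr = ExpressionMatrix.from_frame(raw.astype(float))
    if design is not None:
        expr.check_samples(design)
    return expr


def read_design(path: str | Path, aligned: bool | None = None) -> StudyDesign:
    return StudyDesign.from_frame(_read_table(path), aligned=aligned)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = expr.frame.copy()
    frame.index.name = "protein_id"
    frame.to_csv(path, sep="\t", na_rep="NA")


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.table.loc[:, list(DESIGN_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> Path:
    """Write expression + design + truth TSVs of a simulated dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(dataset.expr, out / "expression.tsv")
    write_design(dataset.design, out / "design.tsv")
    dataset.truth.to_csv(out / "truth.tsv", sep="\t", na_rep="NA")
    return out


def read_dataset(data_dir: str | Path):
    """Read back a simulated dataset directory -> (expr, design, truth)."""
    data_dir = Path(data_dir)
    design = read_design(data_dir / "design.tsv")
    expr = read_expression(data_dir / "expression.tsv", design)
    truth = pd.read_csv(data_dir / "truth.tsv", sep="\t", index_col=0)
    return expr, design, truth


def write_result(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
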