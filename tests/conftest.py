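import numpy as np
import pandas as pd
import pytest

from rolde import ExpressionMatrix, StudyDesign


def make_design(
    n_per_condition: int = 3,
    timepoints=(1.0, 2.0, 3.0, 4.0, 5.0),
    aligned: bool | None = None,
) -> StudyDesign:
    rows = []
    for c in ("C1", "C2"):
        for i in range(n_per_condition):
            ind = f"{c}_i{i + 1}"
            for tp in timepoints:
                rows.append((f"{ind}_t{tp:g}", c, ind, float(tp)))
    return StudyDesign.from_frame(
        pd.DataFrame(rows, columns=["sample_id", "condition", "individual", "timepoint"]),
        aligned=aligned,
    )


def make_expression(design: StudyDesign, values: np.ndarray, prefix: str = "P") -> ExpressionMatrix:
    proteins = [f"{prefix}{i:04d}" for i in range(values.shape[0])]
    return ExpressionMatrix.from_frame(
        pd.DataFrame(values, index=proteins, columns=design.sample_ids)
    )


@pytest.fixture
def design_3v3():
    return make_design(3)


@pytest.fixture
def null_expression(design_3v3):
    """Complete all-null data: per-protein baseline + iid noise."""
    rng = np.random.default_rng(1234)
    n_samples = len(design_3v3.sample_ids)
    values = rng.normal(25, 2, size=(200, 1))[:, [0] * n_samples] + rng.normal(
        0, 0.3, size=(200, n_samples)
    )
    return make_expression(design_3v3, values)
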