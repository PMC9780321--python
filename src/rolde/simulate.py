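"""Semi-simulated longitudinal spike-in benchmark generator.

The generator emulates the structure of label-free spike-in proteomics
benchmarks: a large noisy-but-stable background proteome plus a set of
spike-in proteins whose group means follow predefined longitudinal trend
shapes built from a ladder of L discrete concentration levels (adjacent
levels one configurable log2-step apart, mimicking a 2-4-10-25-50 fmol
dilution series).  Every measured value of protein i in group j (a condition
x timepoint cell) is drawn independently from N(mu_ij, sigma_ij^2), with the
group standard deviations drawn from a log-normal whose median matches a
typical label-free replicate spread.

Trend categories: Stable, Linear, LogLike, Sigmoid, Poly2, PolyHigher.
Missingness is injected either completely at random (MCAR) or left-censored
(MNAR), the latter with an intensity-dependent logistic dropout calibrated
to a target overall rate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, StudyDesign

__all__ = [
    "CATEGORIES",
    "NoiseConfig",
    "SimulatedDataset",
    "trend_profile",
    "enumerate_benchmark",
    "generate_dataset",
    "inject_missing",
    "filter_complete",
    "benchmark_plan",
]

CATEGORIES = ("Stable", "Linear", "LogLike", "Sigmoid", "Poly2", "PolyHigher")

_BASE_T = 5  # shapes are canonical at 5+ points; shorter designs truncate from the front


def _shape(category: str, x: np.ndarray) -> np.ndarray:
    """Canonical trend shape on [0, 1] -> [0, 1] (the 'up' orientation)."""
    if category == "Stable":
        return np.full_like(x, 0.5)
    if category == "Linear":
        return x
    if category == "LogLike":
        return np.log1p(9.0 * x) / np.log(10.0)
    if category == "Sigmoid":
        raw = 1.0 / (1.0 + np.exp(-10.0 * (x - 0.5)))
        lo, hi = 1.0 / (1.0 + np.exp(5.0)), 1.0 / (1.0 + np.exp(-5.0))
        return (raw - lo) / (hi - lo)
    if category == "Poly2":
        return np.abs(2.0 * x - 1.0)  # valley in the 'up' orientation
    if category == "PolyHigher":
        raw = np.sin(3.0 * np.pi * x)  # two interior direction changes
        return (raw + 1.0) / 2.0
    raise ValueError(f"unknown trend category: {category!r}")


def trend_profile(category: str, direction: str, T: int, L: int) -> np.ndarray:
    """Deterministic level sequence (values in 1..L) for a trend category.

    ``direction`` is "up" or "down" (for Poly2 this flips valley/peak;
    ignored for Stable).  Designs with T < 5 truncate the canonical 5-point
    sequence from the front, mirroring how reduced-timepoint benchmark
    variants drop early samples.
    """
    if not 3 <= T <= 10:
        raise ValueError("T must be in 3..10")
    if L < 3:
        raise ValueError("need at least 3 concentration levels")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    t_eff = max(T, _BASE_T)
    x = np.linspace(0.0, 1.0, t_eff)
    f = _shape(category, x)
    levels = np.rint(1.0 + (L - 1) * f).astype(int)
    if category == "Stable":
        levels = np.full(t_eff, int(np.ceil((L + 1) / 2)), dtype=int)
    elif direction == "down":
        levels = L + 1 - levels
    return levels[t_eff - T :]


def enumerate_benchmark(
    categories: tuple[str, ...] = CATEGORIES, exclude_null_pair: bool = False
) -> list[tuple[str, str]]:
    """All unordered condition-pair combinations of trend categories
    (with repetition); optionally without the uninformative (Stable, Stable)."""
    if not categories:
        raise ValueError("categories must be nonempty")
    pairs = list(itertools.combinations_with_replacement(categories, 2))
    if exclude_null_pair:
        pairs = [p for p in pairs if p != ("Stable", "Stable")]
    return pairs


def benchmark_plan() -> pd.DataFrame:
    """The full benchmark inventory: collections, trend combinations and
    dataset counts (15 replicate datasets per informative combination)."""
    rows = [
        # collection, categories, combos (non-null), variants, datasets
        ("UPS1 filtered", 6, 20, 1, 300),
        ("UPS1 full", 6, 20, 1, 300),
        ("SGSDS filtered", 5, 14, 1, 210),
        ("SGSDS full", 5, 14, 1, 210),
        ("UPS1 Mix filtered", 6, 10, 1, 300),
        ("UPS1 Mix full", 6, 10, 1, 300),
        ("CPTAC full", 6, 20, 1, 300),
        ("UPS1 reduced T=3 filtered", 6, 20, 1, 300),
        ("UPS1 reduced T=3 full", 6, 20, 1, 300),
        ("UPS1 reduced T=4 filtered", 6, 20, 1, 300),
        ("UPS1 reduced T=4 full", 6, 20, 1, 300),
    ]
    return pd.DataFrame(
        rows, columns=["collection", "n_categories", "n_combinations", "variants", "n_datasets"]
    )


@dataclass
class NoiseConfig:
    """Generative parameters of the synthetic benchmark.

    baseline_mean / baseline_sd: protein log2 baseline distribution.
    sigma_median / sigma_log_sd: log-normal of the group standard deviations
    (median 0.3 log2 units, a typical label-free replicate spread).
    level_step: log2 distance between adjacent concentration levels.
    n_levels: size of the concentration ladder.
    """

    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    sigma_median: float = 0.3
    sigma_log_sd: float = 0.4
    level_step: float = 1.0
    n_levels: int = 5


@dataclass
class SimulatedDataset:
    expr: ExpressionMatrix
    design: StudyDesign
    truth: pd.DataFrame  # protein_id, is_spikein, trend_c1, trend_c2, direction
    mu: pd.DataFrame | None = None  # protein x group generative means
    sigma: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def generate_dataset(
    n_background: int = 1000,
    n_spikein: int = 50,
    trend_pair: tuple[str, str] = ("Linear", "Stable"),
    T: int = 5,
    n_individuals: int = 3,
    noise: NoiseConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> SimulatedDataset:
    """Generate one two-condition spike-in dataset with ground truth.

    Background proteins share one baseline mean across all groups (the
    no-differential-expression null holds by construction); spike-in protein
    means follow the level ladder of their condition's trend category.
    Spike-in directions alternate deterministically (up, down, up, ...).
    """
    noise = noise or NoiseConfig()
    if n_spikein > n_background:
        warnings.warn("more spike-ins than background proteins is unrealistic", stacklevel=2)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    P = n_background + n_spikein
    L = noise.n_levels
    mid = (L + 1) / 2.0
    cat1, cat2 = trend_pair
    conditions = ("C1", "C2")
    timepoints = np.arange(1, T + 1, dtype=float)

    proteins = [f"BG_{i + 1:04d}" for i in range(n_background)] + [
        f"SPIKE_{i + 1:03d}" for i in range(n_spikein)
    ]
    is_spike = np.array([False] * n_background + [True] * n_spikein)
    directions = np.array(
        ["-"] * n_background + [["up", "down"][i % 2] for i in range(n_spikein)]
    )

    # group means: groups are (condition, timepoint) cells
    baseline = rng.normal(noise.baseline_mean, noise.baseline_sd, size=P)
    groups = [(c, tp) for c in conditions for tp in timepoints]
    mu = np.tile(baseline[:, None], (1, len(groups)))
    for ci, cat in enumerate((cat1, cat2)):
        for si in range(n_spikein):
            p = n_background + si
            levels = trend_profile(cat, directions[p], T, L)
            for ti in range(T):
                mu[p, ci * T + ti] = baseline[p] + (levels[ti] - mid) * noise.level_step

    sigma = rng.lognormal(
        mean=np.log(noise.sigma_median), sigma=noise.sigma_log_sd, size=(P, len(groups))
    )

    # samples: one per (condition, individual, timepoint)
    rows = []
    for ci, c in enumerate(conditions):
        for ii in range(n_individuals):
            ind = f"{c}_ind{ii + 1}"
            for tp in timepoints:
                rows.append((f"{ind}_t{int(tp)}", c, ind, tp))
    design_table = pd.DataFrame(rows, columns=["sample_id", "condition", "individual", "timepoint"])
    design = StudyDesign.from_frame(design_table, aligned=True)

    group_of_sample = [
        groups.index((r.condition, r.timepoint)) for r in design_table.itertuples()
    ]
    values = np.empty((P, len(design_table)))
    for si, gi in enumerate(group_of_sample):
        values[:, si] = rng.normal(mu[:, gi], sigma[:, gi])

    expr = ExpressionMatrix.from_frame(
        pd.DataFrame(values, index=proteins, columns=design_table["sample_id"])
    )
    truth = pd.DataFrame(
        {
            "protein_id": proteins,
            "is_spikein": is_spike,
            "trend_c1": np.where(is_spike, cat1, "Stable"),
            "trend_c2": np.where(is_spike, cat2, "Stable"),
            "direction": directions,
        }
    ).set_index("protein_id")
    group_cols = [f"{c}_t{int(tp)}" for c, tp in groups]
    return SimulatedDataset(
        expr=expr,
        design=design,
        truth=truth,
        mu=pd.DataFrame(mu, index=proteins, columns=group_cols),
        sigma=pd.DataFrame(sigma, index=proteins, columns=group_cols),
        meta={"trend_pair": trend_pair, "T": T, "n_individuals": n_individuals},
    )


def _calibrate_mnar_tau(x: np.ndarray, rate: float, scale: float) -> float:
    """Threshold tau such that the mean logistic dropout probability over the
    observed intensities equals the target rate."""
    lo, hi = x.min() - 20 * scale, x.max() + 20 * scale
    for _ in range(200):
        mid = (lo + hi) / 2.0
        p = 1.0 / (1.0 + np.exp((x - mid) / scale))
        if p.mean() < rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def inject_missing(
    dataset: SimulatedDataset,
    overall_rate: float,
    spikein_rate: float | None = None,
    mechanism: str = "MNAR",
    mnar_scale: float = 0.5,
    seed: int | np.random.SeedSequence | None = None,
) -> SimulatedDataset:
    """Inject missing values; truth labels are unchanged.

    MNAR: left-censoring — dropout probability is a logistic function of
    (negative) intensity, calibrated so the expected overall rate equals the
    target.  MCAR: uniform dropout.  Spike-in proteins can get their own
    target rate (e.g. to emulate benchmarks where spike-ins miss more often).
    """
    if not 0 <= overall_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    if spikein_rate is not None and not 0 <= spikein_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    if mechanism not in ("MNAR", "MCAR"):
        raise ValueError("mechanism must be 'MNAR' or 'MCAR'")
    if overall_rate == 0 and not spikein_rate:
        return dataset

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    values = dataset.expr.values.copy()
    spike = dataset.truth["is_spikein"].to_numpy()
    masks = [(~spike, overall_rate)]
    if spikein_rate is None:
        masks = [(np.ones(len(spike), dtype=bool), overall_rate)]
    else:
        masks.append((spike, spikein_rate))

    for rows, rate in masks:
        if rate == 0 or not rows.any():
            continue
        block = values[rows]
        finite = np.isfinite(block)
        if mechanism == "MCAR":
            drop = rng.random(block.shape) < rate
        else:
            tau = _calibrate_mnar_tau(block[finite], rate, mnar_scale)
            prob = 1.0 / (1.0 + np.exp((block - tau) / mnar_scale))
            drop = rng.random(block.shape) < prob
        block[drop & finite] = np.nan
        values[rows] = block

    expr = ExpressionMatrix.from_frame(
        pd.DataFrame(values, index=dataset.expr.proteins, columns=dataset.expr.samples)
    )
    meta = dict(dataset.meta, missing=dict(mechanism=mechanism, overall_rate=overall_rate,
                                           spikein_rate=spikein_rate))
    return replace(dataset, expr=expr, meta=meta)


def filter_complete(dataset: SimulatedDataset) -> SimulatedDataset:
    """Keep only proteins without any missing value (the 'filtered' variant)."""
    keep = np.isfinite(dataset.expr.values).all(axis=1)
    proteins = [p for p, k in zip(dataset.expr.proteins, keep) if k]
    expr = ExpressionMatrix.from_frame(dataset.expr.frame.loc[proteins])
    truth = dataset.truth.loc[proteins]
    mu = dataset.mu.loc[proteins] if dataset.mu is not None else None
    sigma = dataset.sigma.loc[proteins] if dataset.sigma is not None else None
    return replace(dataset, expr=expr, truth=truth, mu=mu, sigma=sigma)
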