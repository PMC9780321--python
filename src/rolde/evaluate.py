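"""Benchmark evaluation: partial AUC, IQR means, top-k overlap curves.

Scores follow the package convention that smaller = stronger evidence.
Proteins a method could not score are placed randomly at the end of the
result list (random scores strictly above the observed maximum) so that every
method is evaluated on a complete ranking.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["fill_missing_scores", "partial_auc", "iqr_mean", "topk_overlap"]


def fill_missing_scores(
    scores: np.ndarray, seed: int | np.random.SeedSequence | None = None
) -> np.ndarray:
    """Replace missing scores with distinct random values above the observed
    maximum; the relative order of valid scores is unchanged."""
    scores = np.asarray(scores, dtype=float).copy()
    missing = ~np.isfinite(scores)
    if not missing.any():
        return scores
    if missing.all():
        raise ValueError("need at least one valid score")
    rng = np.random.default_rng(seed)
    top = scores[~missing].max()
    span = max(abs(top), 1.0)
    scores[missing] = top + span * (0.5 + rng.random(missing.sum()))
    return scores


def partial_auc(
    scores: np.ndarray,
    truth: np.ndarray,
    spec_lo: float = 0.9,
    standardized: bool = True,
) -> float:
    """Partial AUC on the high-specificity band [spec_lo, 1].

    The ROC area restricted to false positive rate <= 1 - spec_lo (trapezoid
    rule, boundary interpolated, ties giving diagonal segments).  When
    ``standardized``, the raw area is rescaled with the McClish correction
    0.5 * (1 + (A - A_min) / (A_max - A_min)) where A_max is the band width
    and A_min the area of the chance diagonal on the band, so a perfect
    classifier scores 1 and a chance classifier 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be complete; use fill_missing_scores first")
    band = 1.0 - spec_lo
    fpr, tpr, _ = roc_curve(truth, -scores)
    # interpolate the curve at the band edge, then integrate
    tpr_at = np.interp(band, fpr, tpr)
    keep = fpr <= band
    fx = np.concatenate([fpr[keep], [band]])
    fy = np.concatenate([tpr[keep], [tpr_at]])
    raw = float(np.trapezoid(fy, fx))
    if not standardized:
        return raw
    a_min = band * band / 2.0
    a_max = band
    return 0.5 * (1.0 + (raw - a_min) / (a_max - a_min))


def iqr_mean(values: np.ndarray) -> float:
    """Mean of the values inside [Q1, Q3] (quartiles by linear interpolation
    of order statistics)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    q1, q3 = np.percentile(values, [25, 75])
    inside = values[(values >= q1) & (values <= q3)]
    return float(inside.mean())


def topk_overlap(
    score_lists: list[np.ndarray], ks: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Median pairwise proportional overlap of top-k lists as k varies.

    All score lists must cover the same proteins in the same order; top lists
    are formed by ascending score with ties broken by stable index.  Returns
    (ks, overlap curve); the curve ends at 1 when k reaches the list length.
    """
    if len(score_lists) < 2:
        raise ValueError("need at least two result lists")
    n = len(score_lists[0])
    if any(len(s) != n for s in score_lists):
        raise ValueError("result lists must cover the same protein set")
    if ks is None:
        ks = np.arange(1, n + 1)
    ks = np.asarray(ks, dtype=int)

    ranks = []
    for s in score_lists:
        order = np.argsort(np.asarray(s, dtype=float), kind="stable")
        r = np.empty(n, dtype=int)
        r[order] = np.arange(n)
        ranks.append(r)

    curve = np.empty(len(ks), dtype=float)
    pair_counts = []
    for i in range(len(ranks)):
        for j in range(i + 1, len(ranks)):
            m = np.maximum(ranks[i], ranks[j])
            pair_counts.append(np.bincount(m, minlength=n).cumsum())
    pair_counts = np.asarray(pair_counts)
    for ki, k in enumerate(ks):
        curve[ki] = float(np.median(pair_counts[:, k - 1] / k))
    return ks, curve
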