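"""Segmentation and thickness evaluation.

Overlap metrics (Dice, IoU, sensitivity/specificity/precision/F1) are
computed for the RNFL class only, because the band is a small fraction
of the image and whole-image scores would be dominated by background.
Boundary accuracy is the mean unsigned error (MUE) — the mean per-column
absolute row distance between predicted and reference boundaries — and
thickness accuracy is reported as MAE (µm) and MAPE (%) of per-scan mean
thickness.  The axial scale (µm per pixel) is a required parameter: it
depends on the device raster, and thickness in µm is meaningless without
it.  Group comparisons of MAPE follow the nonparametric workflow:
Shapiro–Wilk normality per group, Kruskal–Wallis omnibus, then pairwise
two-sided Mann–Whitney U with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import isnan

import numpy as np
from scipy import stats

from rnflseg.types import BoundarySet, RNFL


def _class_sets(pred_mask: np.ndarray, gt_mask: np.ndarray, cls: int):
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(
            f"mask shapes differ: {pred_mask.shape} vs {gt_mask.shape}"
        )
    return pred_mask == cls, gt_mask == cls


def dice(pred_mask: np.ndarray, gt_mask: np.ndarray, cls: int = RNFL) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) for one class.

    Defined as 1.0 when the class is absent from both masks (perfect
    agreement on absence).
    """
    a, b = _class_sets(pred_mask, gt_mask, cls)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(pred_mask: np.ndarray, gt_mask: np.ndarray, cls: int = RNFL) -> float:
    """Jaccard index |A∩B| / |A∪B| for one class; empty-empty -> 1."""
    a, b = _class_sets(pred_mask, gt_mask, cls)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class SegScores:
    """RNFL-class overlap and confusion metrics; a score whose ratio is
    undefined (zero denominator) is NaN, not 0."""

    dice: float
    iou: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float


def confusion_metrics(
    pred_mask: np.ndarray, gt_mask: np.ndarray, cls: int = RNFL
) -> SegScores:
    """Pixel-wise class-vs-rest confusion scores for one class."""
    a, b = _class_sets(pred_mask, gt_mask, cls)
    tp = float(np.logical_and(a, b).sum())
    fp = float(np.logical_and(a, ~b).sum())
    fn = float(np.logical_and(~a, b).sum())
    tn = float(np.logical_and(~a, ~b).sum())

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    if isnan(sens) or isnan(prec) or prec + sens == 0:
        f1 = float("nan") if isnan(sens) or isnan(prec) else 0.0
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return SegScores(
        dice=dice(pred_mask, gt_mask, cls),
        iou=iou(pred_mask, gt_mask, cls),
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
    )


def extract_boundaries(mask: np.ndarray) -> tuple[BoundarySet, np.ndarray]:
    """Recover per-column band boundaries from a categorical mask.

    Per column, ``upper`` is the first RNFL row and ``lower`` one past
    the last (span convention — robust to non-contiguous RNFL runs in
    network predictions).  Columns without any RNFL pixel are filled by
    linear interpolation from flanking columns (flat at the edges) and
    flagged invalid in the returned validity array.
    """
    mask = np.asarray(mask)
    height, width = mask.shape
    is_band = mask == RNFL
    valid = is_band.any(axis=0)
    if not valid.any():
        raise ValueError("mask contains no RNFL pixels in any column")
    upper = np.zeros(width, dtype=np.int64)
    lower = np.ones(width, dtype=np.int64)
    rr = np.arange(height)
    for c in np.nonzero(valid)[0]:
        rows = rr[is_band[:, c]]
        upper[c] = rows[0]
        lower[c] = rows[-1] + 1
    cols = np.arange(width)
    upper = np.floor(np.interp(cols, cols[valid], upper[valid]) + 0.5).astype(np.int64)
    lower = np.floor(np.interp(cols, cols[valid], lower[valid]) + 0.5).astype(np.int64)
    lower = np.maximum(lower, upper + 1)
    return BoundarySet(upper=upper, lower=lower), valid


def mue(
    pred: BoundarySet,
    gt: BoundarySet,
    boundary: str = "upper",
    axial_scale: float = 1.0,
) -> float:
    """Mean unsigned error of one boundary: mean over columns of
    ``|pred[c] - gt[c]|``, converted to µm by ``axial_scale``."""
    if pred.width != gt.width:
        raise ValueError("boundary sets have different widths")
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    p = getattr(pred, boundary)
    g = getattr(gt, boundary)
    return float(np.mean(np.abs(p - g)) * axial_scale)


def mean_thickness(boundaries: BoundarySet, axial_scale: float = 1.0) -> float:
    """Mean band thickness: column average of (lower - upper) x scale."""
    return float(boundaries.thickness().mean() * axial_scale)


def mae_mape(
    pred_thicknesses: np.ndarray, gt_thicknesses: np.ndarray
) -> tuple[float, float]:
    """MAE (same units as inputs) and MAPE (%) of per-scan thicknesses."""
    pred = np.asarray(pred_thicknesses, dtype=float)
    gt = np.asarray(gt_thicknesses, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground-truth lists differ in length")
    if np.any(gt <= 0):
        raise ValueError("MAPE undefined: nonpositive ground-truth thickness")
    err = np.abs(pred - gt)
    return float(err.mean()), float(100.0 * (err / gt).mean())


@dataclass
class GroupStatsReport:
    """Machine-readable record of the group-comparison workflow."""

    shapiro: dict[str, tuple[float, float]]
    kruskal: tuple[float, float]
    pairwise: dict[tuple[str, str], tuple[float, float, bool]]
    alpha: float
    alpha_adjusted: float
    rows: list[dict] = field(default_factory=list)


def group_stats(
    samples_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> GroupStatsReport:
    """Nonparametric comparison of a metric across diagnostic groups.

    Per-group Shapiro–Wilk tests justify (or not) the nonparametric
    route; Kruskal–Wallis tests for any overall difference; all pairwise
    two-sided Mann–Whitney U tests follow, judged at the
    Bonferroni-adjusted level ``alpha / n_pairs``.  Mann–Whitney uses the
    exact null distribution when both groups have n <= 20 and no ties,
    and the tie-corrected normal approximation otherwise.
    """
    if len(samples_by_group) < 2:
        raise ValueError("need at least two groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in samples_by_group.items()}
    for name, x in groups.items():
        if x.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")

    rows: list[dict] = []
    shapiro = {}
    for name, x in groups.items():
        w, p = stats.shapiro(x)
        shapiro[name] = (float(w), float(p))
        rows.append(
            {"test": "shapiro-wilk", "comparison": name, "statistic": float(w),
             "p": float(p),
             "interpretation": "non-normal" if p < alpha else "normal"}
        )

    h, p_kw = stats.kruskal(*groups.values())
    kruskal = (float(h), float(p_kw))
    rows.append(
        {"test": "kruskal-wallis", "comparison": "all groups",
         "statistic": float(h), "p": float(p_kw),
         "interpretation": "significant" if p_kw < alpha else "not significant"}
    )

    pairs = list(combinations(sorted(groups), 2))
    alpha_adj = alpha / len(pairs)
    pairwise = {}
    for g1, g2 in pairs:
        x, y = groups[g1], groups[g2]
        small = x.size <= 20 and y.size <= 20
        no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
        method = "exact" if (small and no_ties) else "asymptotic"
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        sig = bool(p < alpha_adj)
        pairwise[(g1, g2)] = (float(u), float(p), sig)
        rows.append(
            {"test": "mann-whitney-u", "comparison": f"{g1} vs {g2}",
             "statistic": float(u), "p": float(p),
             "interpretation": "significant" if sig else "not significant"}
        )

    return GroupStatsReport(
        shapiro=shapiro,
        kruskal=kruskal,
        pairwise=pairwise,
        alpha=alpha,
        alpha_adjusted=alpha_adj,
        rows=rows,
    )
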