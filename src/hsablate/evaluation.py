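"""Segmentation/regression metrics, margin extraction and correlation.

Conventions
-----------
* DICE of two empty masks is 1.0 (perfect agreement on "nothing there");
  non-empty truth vs empty prediction gives 0.
* Per-class accuracy is one-vs-rest binary accuracy over evaluated pixels.
* The per-pixel relative-error map is signed, ``(pred - actual)/actual*100``;
  the aggregated MRE takes the absolute value.
* Aggregation across procedures: metric per procedure first, then mean +- sd;
  the sd is reported only when n >= 3.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .io import EXCLUDED, NO_DAMAGE, RING, THERMO


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(mask_a: np.ndarray, mask_b: np.ndarray, eval_mask: np.ndarray | None = None) -> float:
    """DICE overlap ``2|A n B| / (|A| + |B|)``; both-empty -> 1.0."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    _check_same_shape(mask_a, mask_b)
    if eval_mask is not None:
        mask_a = mask_a & eval_mask
        mask_b = mask_b & eval_mask
    denom = mask_a.sum() + mask_b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(mask_a, mask_b).sum() / denom)


def per_class_accuracy(
    pred: np.ndarray,
    truth: np.ndarray,
    cls: int,
    eval_mask: np.ndarray | None = None,
) -> float:
    """One-vs-rest binary accuracy for class *cls* over evaluated pixels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_same_shape(pred, truth)
    if eval_mask is None:
        eval_mask = np.ones(pred.shape, dtype=bool)
    eval_mask = eval_mask & (pred != EXCLUDED) & (truth != EXCLUDED)
    n = eval_mask.sum()
    if n == 0:
        raise ValueError("no evaluated pixels")
    agree = (pred == cls) == (truth == cls)
    return float(agree[eval_mask].sum() / n)


def relative_error_map(
    pred: np.ndarray,
    actual: np.ndarray,
    eval_mask: np.ndarray | None = None,
    eps: float = 1.0,
) -> np.ndarray:
    """Signed per-pixel relative error in %, NaN outside the evaluated set."""
    pred = np.asarray(pred, dtype=np.float64)
    actual = np.asarray(actual, dtype=np.float64)
    _check_same_shape(pred, actual)
    if eval_mask is None:
        eval_mask = np.isfinite(pred) & np.isfinite(actual)
    else:
        eval_mask = eval_mask & np.isfinite(pred) & np.isfinite(actual)
    if np.any(actual[eval_mask] < eps):
        raise ValueError(f"actual peak below {eps} degC inside the evaluated region")
    out = np.full(pred.shape, np.nan)
    out[eval_mask] = (pred[eval_mask] - actual[eval_mask]) / actual[eval_mask] * 100.0
    return out


def mre(rel_err_map: np.ndarray, region_mask: np.ndarray | None = None) -> float | None:
    """Mean of ``|relative error|`` (%) over a region; ``None`` (missing, not
    zero) when the region holds no evaluated pixels."""
    rel = np.asarray(rel_err_map, dtype=np.float64)
    if region_mask is None:
        region_mask = np.ones(rel.shape, dtype=bool)
    vals = rel[region_mask & np.isfinite(rel)]
    if vals.size == 0:
        return None
    return float(np.mean(np.abs(vals)))


def aggregate(values: list[float]) -> tuple[float, float | None]:
    """Mean and sd across procedures; sd only when n >= 3."""
    vals = [v for v in values if v is not None]
    if not vals:
        raise ValueError("nothing to aggregate")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 3 else None
    return mean, sd


# ---------------------------------------------------------------------------
# Margins
# ---------------------------------------------------------------------------


def margin_from_peakmap(
    peak: np.ndarray, t_star: float = 50.6, roi_mask: np.ndarray | None = None
) -> np.ndarray:
    """Damage mask by thresholding a peak-temperature map at ``T*``."""
    peak = np.asarray(peak, dtype=np.float64)
    mask = peak >= t_star
    if roi_mask is not None:
        mask = mask & roi_mask
    return mask


def margin_from_labels(labels: np.ndarray) -> np.ndarray:
    """Total-damage mask from a label map: ring u thermo."""
    labels = np.asarray(labels)
    return (labels == RING) | (labels == THERMO)


def compare_margins(
    mask_a: np.ndarray, mask_b: np.ndarray, eval_mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Binary (DICE, accuracy) agreement between two damage masks."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    _check_same_shape(mask_a, mask_b)
    if eval_mask is None:
        eval_mask = np.ones(mask_a.shape, dtype=bool)
    d = dice(mask_a, mask_b, eval_mask)
    n = eval_mask.sum()
    if n == 0:
        raise ValueError("no evaluated pixels")
    acc = float((mask_a == mask_b)[eval_mask].sum() / n)
    return d, acc


# ---------------------------------------------------------------------------
# Correlation / agreement
# ---------------------------------------------------------------------------


def pearson_correlation(x, y) -> tuple[float, float, float]:
    """Product-moment ``(r, r^2, two-tailed p)``; p from the t distribution
    with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined correlation")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def inter_annotator_agreement(
    ann_a: np.ndarray,
    ann_b: np.ndarray,
    eval_mask: np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-class (DICE, accuracy) between two annotators, A as reference."""
    ann_a = np.asarray(ann_a)
    ann_b = np.asarray(ann_b)
    _check_same_shape(ann_a, ann_b)
    out = {}
    for cls, name in ((NO_DAMAGE, "no_damage"), (RING, "ring"), (THERMO, "thermo")):
        d = dice(ann_a == cls, ann_b == cls, eval_mask)
        acc = per_class_accuracy(ann_b, ann_a, cls, eval_mask)
        out[name] = (d, acc)
    return out
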