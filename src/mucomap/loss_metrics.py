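"""Combined segmentation loss (soft Jaccard distance + cross-entropy) and
evaluation metrics (MIoU, Dice).

The training objective is

    l = l_Jaccard-distance + l_cross-entropy

with the Jaccard-distance part a per-pixel soft IoU,

    l_jd = 1 - (1/N) sum_i (p_i * y_i + eps) / (p_i + y_i - p_i * y_i + eps),

where p_i in [0, 1] is the predicted probability, y_i in {0, 1} the one-hot
label, and N the number of summed terms.  The smoothing constant eps
(default 1) makes the 0/0 summand of an empty-vs-empty pixel contribute a
perfect-overlap term, standard soft-Jaccard practice.  The cross-entropy
part is the conventional -(1/N_pixels) sum_i sum_c y_ic log p_ic, normalized
by pixel count so both parts are comparable across batch sizes.

Evaluation metrics are computed from hard label maps via pixel counts:
per-class IoU = |P ∩ T| / |P ∪ T|, Dice = 2|P ∩ T| / (|P| + |T|); a class
absent from both prediction and truth is excluded from the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: floor for log arguments so hard-0 predictions keep the loss finite
LOG_CLIP = 1e-7


@dataclass(frozen=True)
class LossValue:
    """Combined loss with its two parts reported separately."""

    total: float
    jaccard_part: float
    ce_part: float


def _check_pair(p, y):
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    return p, y


def jaccard_distance_loss(p, y, smooth: float = 1.0) -> float:
    """Soft Jaccard distance between predictions ``p`` and labels ``y``.

    Every element is treated as one summand (for multi-class one-hot input
    this averages over pixels and class channels alike).  Lies in [0, 1];
    0 exactly when p == y and both are binary.
    """
    p, y = _check_pair(p, y)
    if smooth < 0:
        raise ValueError("smooth must be >= 0")
    num = p * y + smooth
    den = p + y - p * y + smooth
    if smooth == 0:
        # 0/0 terms (p = y = 0) count as perfect overlap
        terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    else:
        terms = num / den
    return float(1.0 - terms.mean())


def cross_entropy_loss(p, y, clip: float = LOG_CLIP, channel_axis: int | None = -1) -> float:
    """Pixel-averaged cross-entropy -(1/N) sum_pixels sum_classes y log p.

    ``channel_axis`` names the class axis; pass ``None`` for single-channel
    input where every element is its own pixel.
    """
    p, y = _check_pair(p, y)
    total = float(-(y * np.log(np.maximum(p, clip))).sum())
    n_pixels = p.size if channel_axis is None else p.size // p.shape[channel_axis]
    return total / max(n_pixels, 1)


def combined_loss(p, y, smooth: float = 1.0, channel_axis: int | None = -1) -> LossValue:
    """Jaccard-distance + cross-entropy, parts reported separately."""
    jd = jaccard_distance_loss(p, y, smooth)
    ce = cross_entropy_loss(p, y, channel_axis=channel_axis)
    return LossValue(total=jd + ce, jaccard_part=jd, ce_part=ce)


def combined_loss_grad(p, y, smooth: float = 1.0, channel_axis: int = -1):
    """Gradient of the combined loss w.r.t. the probabilities ``p``.

    Used by the training loop (the network chains this through its softmax).
    Returns an array of ``p``'s shape.
    """
    p, y = _check_pair(p, y)
    n_terms = p.size
    n_pixels = p.size // p.shape[channel_axis]
    # d/dp of -(1/n_terms) * (p y + eps)/(p + y - p y + eps)
    u = p * y + smooth
    v = p + y - p * y + smooth
    g_jd = -(y * v - u * (1.0 - y)) / (v * v) / n_terms
    # d/dp of -(1/n_pixels) y log(max(p, clip)): zero in the clipped region
    pc = np.maximum(p, LOG_CLIP)
    g_ce = np.where(p >= LOG_CLIP, -y / pc, 0.0) / n_pixels
    return g_jd + g_ce


# ---------------------------------------------------------------------------
# hard-label metrics


def confusion_counts(pred, truth, num_classes: int) -> np.ndarray:
    """(K, K) matrix of pixel counts, rows = truth class, cols = predicted."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    if pred.size and (pred.max() >= num_classes or truth.max() >= num_classes):
        raise ValueError("labels must be < num_classes")
    idx = truth.astype(np.int64).ravel() * num_classes + pred.astype(np.int64).ravel()
    return np.bincount(idx, minlength=num_classes**2).reshape(num_classes, num_classes)


def per_class_iou(pred, truth, num_classes: int) -> np.ndarray:
    """IoU per class; NaN for classes absent from both maps."""
    cm = confusion_counts(pred, truth, num_classes)
    inter = np.diag(cm).astype(np.float64)
    union = cm.sum(axis=0) + cm.sum(axis=1) - np.diag(cm)
    with np.errstate(invalid="ignore"):
        return np.where(union > 0, inter / np.maximum(union, 1), np.nan)


def per_class_dice(pred, truth, num_classes: int) -> np.ndarray:
    """Dice per class; NaN for classes absent from both maps."""
    cm = confusion_counts(pred, truth, num_classes)
    inter = np.diag(cm).astype(np.float64)
    sizes = cm.sum(axis=0) + cm.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(sizes > 0, 2.0 * inter / np.maximum(sizes, 1), np.nan)


def miou(pred, truth, num_classes: int) -> float:
    """Mean IoU over the classes present in prediction or truth."""
    return float(np.nanmean(per_class_iou(pred, truth, num_classes)))


def dice(pred, truth, num_classes: int) -> float:
    """Mean Dice over the classes present in prediction or truth."""
    return float(np.nanmean(per_class_dice(pred, truth, num_classes)))


def evaluation_report(pairs, num_classes: int) -> dict:
    """Per-item and aggregate MIoU/Dice (mean ± sd) for (pred, truth) pairs.

    Returns a JSON-serializable dict mirroring the usual "mean ± sd over
    test patches" reporting shape.
    """
    per_item = [
        {"miou": miou(p, t, num_classes), "dice": dice(p, t, num_classes)}
        for p, t in pairs
    ]
    if not per_item:
        raise ValueError("no evaluation pairs")
    mious = np.array([r["miou"] for r in per_item])
    dices = np.array([r["dice"] for r in per_item])
    return {
        "per_item": per_item,
        "aggregate": {
            "miou_mean": float(mious.mean()),
            "miou_sd": float(mious.std(ddof=1)) if len(mious) > 1 else 0.0,
            "dice_mean": float(dices.mean()),
            "dice_sd": float(dices.std(ddof=1)) if len(dices) > 1 else 0.0,
            "n": len(per_item),
        },
    }
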