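"""Cost function and evaluation metrics for binary segmentation.

The soft Dice score ``2*sum(p*y) / (sum(p^2) + sum(y^2))`` (averaged over
objects) doubles as the training objective; evaluation adds Matthews
correlation, sensitivity and the symmetric Hausdorff distance between
boundary pixel sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .imaging import BinaryMask

__all__ = [
    "ConfusionCounts",
    "dice_cost",
    "dice_score",
    "confusion",
    "mcc",
    "sensitivity",
    "boundary_pixels",
    "hausdorff",
    "evaluate_pair",
    "aggregate",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("ds", "mcc", "sen", "hsd")

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _arr(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.data
    return np.asarray(mask)


def dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Soft Dice for one object: 2*sum(p*y) / (sum(p^2) + sum(y^2)).

    On binary inputs this is the classic Dice 2|P&Y|/(|P|+|Y|). When both
    pred and truth are entirely zero the score is defined as 1 (a correctly
    predicted absent object should not poison aggregates).
    """
    p = _arr(pred).astype(np.float64)
    y = _arr(truth).astype(np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    denom = float((p * p).sum() + (y * y).sum())
    if denom == 0.0:
        return 1.0
    return float(2.0 * (p * y).sum() / denom)


def dice_cost(pred, truth) -> float:
    """Mean soft Dice over K objects; the quantity training maximizes.

    ``pred`` and ``truth`` are stacks of shape (K, H, W) (a single (H, W)
    pair is treated as K=1).
    """
    p = np.asarray(pred, dtype=np.float64)
    y = _arr(truth).astype(np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if p.ndim == 2:
        p, y = p[None], y[None]
    if p.ndim != 3 or p.shape[0] < 1:
        raise ValueError(f"expected (K, H, W) stacks, got shape {p.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("pred values must lie in [0, 1]")
    return float(np.mean([dice_score(pk, yk) for pk, yk in zip(p, y)]))


def confusion(pred, truth) -> ConfusionCounts:
    p = _arr(pred).astype(bool)
    y = _arr(truth).astype(bool)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    tp = int(np.count_nonzero(p & y))
    fp = int(np.count_nonzero(p & ~y))
    fn = int(np.count_nonzero(~p & y))
    tn = int(np.count_nonzero(~p & ~y))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation; 0 when any denominator factor vanishes."""
    tp, fp, tn, fn = (float(c.tp), float(c.fp), float(c.tn), float(c.fn))
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0.0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom_sq))


def sensitivity(c: ConfusionCounts) -> float:
    """Recall tp/(tp+fn); an empty truth is perfectly recalled (1)."""
    denom = c.tp + c.fn
    if denom == 0:
        return 1.0
    return float(c.tp / denom)


def boundary_pixels(mask) -> np.ndarray:
    """(n, 2) array of (row, col) boundary coordinates.

    A mask pixel is a boundary pixel when at least one 4-neighbor is zero,
    where out-of-grid neighbors count as zero (so object pixels on the image
    border are boundary).
    """
    arr = _arr(mask).astype(bool)
    interior = ndimage.binary_erosion(arr, structure=_CROSS, border_value=0)
    return np.argwhere(arr & ~interior)


def hausdorff(pred, truth) -> float:
    """Symmetric Euclidean Hausdorff distance between boundary pixel sets."""
    xs = boundary_pixels(pred)
    ys = boundary_pixels(truth)
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError(
            "Hausdorff distance is undefined: at least one mask has no "
            "boundary pixels (empty mask)"
        )
    d_xy = cKDTree(ys).query(xs)[0].max()
    d_yx = cKDTree(xs).query(ys)[0].max()
    return float(max(d_xy, d_yx))


def evaluate_pair(pred, truth) -> dict[str, float]:
    """All four metrics for one (pred, truth) mask pair.

    ``hsd`` is NaN when undefined (either mask empty) so degenerate
    predictions can still be aggregated.
    """
    c = confusion(pred, truth)
    try:
        hsd = hausdorff(pred, truth)
    except ValueError:
        hsd = float("nan")
    return {
        "ds": dice_score(_arr(pred).astype(np.float64), _arr(truth).astype(np.float64)),
        "mcc": mcc(c),
        "sen": sensitivity(c),
        "hsd": hsd,
    }


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    vals = values[~np.isnan(values)]
    if len(vals) == 0:
        return float("nan"), float("nan")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd


def aggregate(rows: pd.DataFrame | Iterable[Mapping]) -> pd.DataFrame:
    """Per-object mean +/- sample SD of each metric, plus a pooled
    ``Overall`` row across all objects and images.

    ``rows`` must provide columns ``object, image_id, ds, mcc, sen, hsd``.
    """
    df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ValueError("aggregate requires at least one row")
    df = df.sort_values(["object", "image_id"], kind="stable")
    out_rows = []
    groups = [(obj, sub) for obj, sub in df.groupby("object", sort=True)]
    groups.append(("Overall", df))
    for obj, sub in groups:
        row: dict[str, object] = {"object": obj, "n": len(sub)}
        for m in METRIC_COLUMNS:
            mean, sd = _mean_sd(sub[m].to_numpy(dtype=np.float64))
            row[f"{m}_mean"] = mean
            row[f"{m}_sd"] = sd
        out_rows.append(row)
    return pd.DataFrame(out_rows)
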