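"""Slide-level evaluation: confusion matrix, AC/SP/SE/PC, heatmaps.

Positive (1) = cancerous, negative (0) = normal.  Accuracy, specificity
(recognition of normal slides), sensitivity/recall (recognition of
cancerous slides) and precision are reported as percentages rounded
half-up to two decimals; ratios with a zero denominator are reported as
missing (NA) with a warning rather than raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "metrics",
    "round2",
    "positive_percentage",
    "heatmap",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (the printing convention used here)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """AC/SP/SE/PC as 2-decimal percentages; raw fractions kept alongside."""

    ac: float | None
    sp: float | None
    se: float | None
    pc: float | None
    raw: dict
    cm: ConfusionMatrix

    def to_dict(self) -> dict:
        return {"AC": self.ac, "SP": self.sp, "SE": self.se, "PC": self.pc}


def confusion(gt, pred) -> ConfusionMatrix:
    """Counts of TP/TN/FP/FN; labels must be 0 (normal) or 1 (cancerous)."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("gt and pred lengths differ")
    for arr in (gt, pred):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
    return ConfusionMatrix(
        tp=int(np.sum((gt == 1) & (pred == 1))),
        tn=int(np.sum((gt == 0) & (pred == 0))),
        fp=int(np.sum((gt == 0) & (pred == 1))),
        fn=int(np.sum((gt == 1) & (pred == 0))),
    )


def _pct(num: int, den: int, name: str) -> tuple[float | None, float | None]:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NA")
        return None, None
    frac = num / den
    return round2(100.0 * frac), frac


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """AC, SP, SE, PC from a confusion matrix (percentages, 2 decimals)."""
    if min(cm.tp, cm.tn, cm.fp, cm.fn) < 0:
        raise ValueError("negative counts")
    ac, ac_raw = _pct(cm.tp + cm.tn, cm.total, "AC")
    sp, sp_raw = _pct(cm.tn, cm.tn + cm.fp, "SP")
    se, se_raw = _pct(cm.tp, cm.tp + cm.fn, "SE")
    pc, pc_raw = _pct(cm.tp, cm.tp + cm.fp, "PC")
    return MetricReport(
        ac=ac, sp=sp, se=se, pc=pc,
        raw={"AC": ac_raw, "SP": sp_raw, "SE": se_raw, "PC": pc_raw},
        cm=cm,
    )


def positive_percentage(labels) -> float:
    """Positive-sample percentage of a label list, 2 decimals."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty label list")
    return round2(100.0 * np.mean(labels == 1))


def heatmap(
    coords: np.ndarray,
    scores: np.ndarray,
    slide_dims: tuple[int, int],
    tile_size: int = 512,
    downsample: int = 8,
    cmap: str = "jet",
    background: np.ndarray | None = None,
    alpha: float = 0.5,
) -> np.ndarray:
    """Paint per-tile attention scores at their recorded coordinates.

    Scores are min-max normalized (a constant score field paints a
    uniform map) and colormapped; with ``background`` given, the map is
    alpha-blended over the downsampled slide image.  Returns an RGB
    uint8 image at 1/downsample scale.
    """
    from matplotlib import colormaps

    coords = np.asarray(coords).reshape(-1, 2)
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    if len(coords) != len(scores):
        raise ValueError("coords/scores length mismatch")
    w, h = slide_dims
    hw, hh = max(w // downsample, 1), max(h // downsample, 1)
    field = np.zeros((hh, hw))
    painted = np.zeros((hh, hw), dtype=bool)
    rng_span = scores.max() - scores.min()
    norm = (scores - scores.min()) / rng_span if rng_span > 0 else np.ones_like(scores)
    ts = max(tile_size // downsample, 1)
    for (x, y), v in zip(coords, norm):
        xs, ys = x // downsample, y // downsample
        field[ys : ys + ts, xs : xs + ts] = v
        painted[ys : ys + ts, xs : xs + ts] = True
    rgba = colormaps[cmap](field)
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    if background is not None:
        bg = np.asarray(background[::downsample, ::downsample, :3])[:hh, :hw]
        out = bg.astype(np.float64).copy()
        out[painted] = (1 - alpha) * bg[painted] + alpha * rgb[painted]
        return out.astype(np.uint8)
    rgb[~painted] = 255
    return rgb
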