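"""Pixel-level segmentation scores: IoU, precision, recall on binarized foreground.

Both masks are reduced to binary foreground (any positive label) before
counting, so these scores measure where cells were found, not how they were
partitioned into instances. Object-level partitioning errors are the domain
of :mod:`cyanobench.object_errors`; a mask that splits every cell in two can
still score near-perfect here, which is exactly why both views are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mask_model import LabeledMask, MaskMovie

__all__ = ["PixelMetrics", "pixel_scores", "movie_pixel_scores", "pixel_report_frame"]


class DimensionError(ValueError):
    """Raised when ground-truth and prediction geometries disagree."""


@dataclass(frozen=True)
class PixelMetrics:
    """Foreground-pixel agreement between a predicted and a reference mask.

    ``iou = tp/(tp+fp+fn)``, ``precision = tp/(tp+fp)``, ``recall =
    tp/(tp+fn)``. Ratios with a zero denominator are reported as 0, except
    the fully vacuous case (both masks empty everywhere) which is reported
    as 1 with ``vacuous=True`` — empty against empty is truthfully perfect
    agreement.
    """

    tp_px: int
    fp_px: int
    fn_px: int
    vacuous: bool = False

    @property
    def iou(self) -> float:
        return self._ratio(self.tp_px, self.tp_px + self.fp_px + self.fn_px)

    @property
    def precision(self) -> float:
        return self._ratio(self.tp_px, self.tp_px + self.fp_px)

    @property
    def recall(self) -> float:
        return self._ratio(self.tp_px, self.tp_px + self.fn_px)

    def _ratio(self, num: int, den: int) -> float:
        if den == 0:
            return 1.0 if self.vacuous else 0.0
        return num / den


def _counts(gt: LabeledMask, pred: LabeledMask) -> tuple[int, int, int]:
    if gt.shape != pred.shape:
        raise DimensionError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    g = gt.pixels > 0
    p = pred.pixels > 0
    tp = int(np.count_nonzero(g & p))
    fp = int(np.count_nonzero(~g & p))
    fn = int(np.count_nonzero(g & ~p))
    return tp, fp, fn


def pixel_scores(gt: LabeledMask, pred: LabeledMask) -> PixelMetrics:
    """Score one predicted frame against its ground truth, pixel by pixel."""
    tp, fp, fn = _counts(gt, pred)
    return PixelMetrics(tp, fp, fn, vacuous=(tp + fp + fn) == 0)


def movie_pixel_scores(gt: MaskMovie, pred: MaskMovie) -> PixelMetrics:
    """Micro-averaged scores over a whole movie.

    True/false positive and negative pixel counts are pooled over all
    frames before the ratios are formed, so frames with few cells do not
    dominate the aggregate.
    """
    if len(gt) != len(pred):
        raise DimensionError(f"frame-count mismatch: gt {len(gt)} vs pred {len(pred)}")
    tp = fp = fn = 0
    for g, p in zip(gt, pred):
        t, f, n = _counts(g, p)
        tp, fp, fn = tp + t, fp + f, fn + n
    return PixelMetrics(tp, fp, fn, vacuous=(tp + fp + fn) == 0)


def pixel_report_frame(gt: MaskMovie, pred: MaskMovie) -> pd.DataFrame:
    """Per-frame score table plus a pooled row (frame = ``"pooled"``)."""
    if len(gt) != len(pred):
        raise DimensionError(f"frame-count mismatch: gt {len(gt)} vs pred {len(pred)}")
    rows = []
    for g, p in zip(gt, pred):
        m = pixel_scores(g, p)
        rows.append((g.frame_index, m))
    rows.append(("pooled", movie_pixel_scores(gt, pred)))
    return pd.DataFrame(
        [
            {
                "frame": fr,
                "tp_px": m.tp_px,
                "fp_px": m.fp_px,
                "fn_px": m.fn_px,
                "iou": m.iou,
                "precision": m.precision,
                "recall": m.recall,
            }
            for fr, m in rows
        ]
    )
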