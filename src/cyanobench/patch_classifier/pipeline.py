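"""Centroid-crop classification pipeline.

Given a labeled mask and the matching multi-channel image, each cell is
cropped as a fixed 32×32 window centered on its mask centroid, fed to the
classifier, and recorded as one CSV row carrying the centroid, the full
probability vector and the argmax class. The same table drives mask
recoloring (class maps for visual inspection) and confusion-matrix
evaluation against per-cell truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..mask_model import ImageStack, LabeledMask, object_inventory
from .network import TrainedClassifier

__all__ = [
    "extract_patch",
    "classify_cells",
    "recolor_mask",
    "evaluate_classification",
    "ClassificationScores",
    "classification_csv_columns",
]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def extract_patch(
    stack: ImageStack,
    mask: LabeledMask,
    label: int,
    patch_size: int = 32,
) -> np.ndarray:
    """Crop a ``patch_size``² window centered on one object's centroid.

    The centroid is rounded to the nearest pixel (half away from zero) and
    the window spans ``[c - 16, c + 16)`` on each axis. Windows that run
    past the image edge are filled by reflection padding, so corner cells
    crop without error. Returns (patch_size, patch_size, C), channel-last.
    """
    if stack.shape != mask.shape:
        raise ValueError(f"stack shape {stack.shape} != mask shape {mask.shape}")
    ys, xs = np.nonzero(mask.pixels == label)
    if ys.size == 0:
        raise KeyError(f"label {label} not present in mask")
    r0 = _round_half_away(float(ys.mean()))
    c0 = _round_half_away(float(xs.mean()))
    half = patch_size // 2
    img = stack.as_array()  # (H, W, C)
    padded = np.pad(img, ((half, half), (half, half), (0, 0)), mode="reflect")
    r, c = r0 + half, c0 + half
    return padded[r - half : r + half, c - half : c + half, :]


def classification_csv_columns(class_names: tuple[str, ...]) -> list[str]:
    return (
        ["frame", "label", "centroid_row", "centroid_col"]
        + [f"prob_{n}" for n in class_names]
        + ["predicted_class", "predicted_name"]
    )


def classify_cells(
    model: TrainedClassifier,
    stack: ImageStack,
    mask: LabeledMask,
) -> pd.DataFrame:
    """Classify every object in a mask: one table row per (frame, label).

    Columns: frame, label, centroid_row, centroid_col, one ``prob_<name>``
    per class, ``predicted_class`` (integer class index; argmax, ties to
    the lowest index) and ``predicted_name``.
    """
    if stack.n_channels != model.config.n_channels:
        raise ValueError(
            f"stack has {stack.n_channels} channels but the model expects "
            f"{model.config.n_channels}"
        )
    inv = object_inventory(mask)
    cols = classification_csv_columns(model.class_names)
    if len(inv) == 0:
        return pd.DataFrame(columns=cols)
    patches = np.stack(
        [
            extract_patch(stack, mask, int(lbl), model.config.patch_size)
            for lbl in inv["label"]
        ]
    )
    probs = model.predict_proba(patches)
    pred = probs.argmax(axis=1)  # np.argmax returns the first (lowest) maximum
    out = pd.DataFrame(
        {
            "frame": np.full(len(inv), mask.frame_index, dtype=np.int64),
            "label": inv["label"].to_numpy(),
            "centroid_row": inv["centroid_row"].to_numpy(),
            "centroid_col": inv["centroid_col"].to_numpy(),
        }
    )
    for k, name in enumerate(model.class_names):
        out[f"prob_{name}"] = probs[:, k]
    out["predicted_class"] = pred.astype(np.int64)
    out["predicted_name"] = [model.class_names[i] for i in pred]
    return out[cols]


def recolor_mask(mask: LabeledMask, table: pd.DataFrame) -> np.ndarray:
    """Replace each object's pixels by its predicted class code.

    The class map uses 0 for background and ``predicted_class + 1`` for
    cells, so class 0 remains distinguishable from background.
    """
    table_labels = set(int(l) for l in table["label"])
    missing = [int(l) for l in mask.labels if int(l) not in table_labels]
    if missing:
        raise KeyError(f"labels missing from classification table: {missing}")
    out = np.zeros(mask.shape, dtype=np.int32)
    lut = dict(zip(table["label"].astype(int), table["predicted_class"].astype(int)))
    for lbl in mask.labels:
        out[mask.pixels == lbl] = lut[int(lbl)] + 1
    return out


@dataclass(frozen=True)
class ClassificationScores:
    """Confusion matrix (rows = truth, cols = predicted) and pooled scores.

    Precision, recall and IoU are micro-averaged over cells: per-class
    true/false positive/negative counts are pooled across classes before
    the ratios are formed. For single-label multi-class data the pooled
    precision and recall both equal the accuracy, and the pooled Jaccard
    index is ``a / (2 - a)`` for accuracy ``a``.
    """

    confusion: np.ndarray
    class_names: tuple[str, ...]

    @property
    def n_cells(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        n = self.n_cells
        return float(np.trace(self.confusion)) / n if n else 1.0

    @property
    def precision(self) -> float:
        tp = float(np.trace(self.confusion))
        fp = float(self.confusion.sum() - np.trace(self.confusion))
        return tp / (tp + fp) if (tp + fp) else 1.0

    @property
    def recall(self) -> float:
        tp = float(np.trace(self.confusion))
        fn = float(self.confusion.sum() - np.trace(self.confusion))
        return tp / (tp + fn) if (tp + fn) else 1.0

    @property
    def iou(self) -> float:
        tp = float(np.trace(self.confusion))
        off = float(self.confusion.sum() - np.trace(self.confusion))
        den = tp + 2 * off  # pooled fp + fn = twice the off-diagonal mass
        return tp / den if den else 1.0


def evaluate_classification(
    table: pd.DataFrame,
    truth: pd.DataFrame,
    class_names: tuple[str, ...] | None = None,
) -> ClassificationScores:
    """Score predictions against per-cell truth labels.

    ``truth`` must carry columns ``frame``, ``label``, ``true_class``
    (integer class index) with exactly the same (frame, label) key set as
    the prediction table; any mismatch raises with the offending keys.
    """
    tkeys = set(zip(table["frame"].astype(int), table["label"].astype(int)))
    ukeys = set(zip(truth["frame"].astype(int), truth["label"].astype(int)))
    if tkeys != ukeys:
        only_pred = sorted(tkeys - ukeys)[:10]
        only_truth = sorted(ukeys - tkeys)[:10]
        raise KeyError(
            f"(frame, label) key mismatch; only in predictions: {only_pred}, "
            f"only in truth: {only_truth}"
        )
    merged = table.merge(truth, on=["frame", "label"], validate="one_to_one")
    n_classes = len(class_names) if class_names else int(
        max(merged["true_class"].max(), merged["predicted_class"].max()) + 1
    )
    names = class_names or tuple(f"class_{i}" for i in range(n_classes))
    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(
        conf,
        (merged["true_class"].to_numpy(int), merged["predicted_class"].to_numpy(int)),
        1,
    )
    return ClassificationScores(conf, tuple(names))
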