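"""Detector interface, reference phantom detector, and AP/mAP evaluation.

Bounding boxes are 0-based, half-open ``[x_min, x_max) x [y_min, y_max)``.
Average precision is the all-point interpolated area under the
precision-recall curve at IoU >= 0.5, the convention used for modern
region-proposal detectors; mAP averages AP over classes with at least one
ground-truth box.  A trained detection network is out of scope here —
external detector backends plug in by emitting the standard detection
table — but :func:`reference_detect` provides a deterministic
template-layout detector that is exact on phantom renderings, so the
downstream temporal logic can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .dataio import STRUCTURE_CLASSES, FrameStack, new_detection_table
from .phantom import BACKGROUND, CONTRAST_DEPTH, layout_anchors


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open pixel box with positive area."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"box must have positive area: {self}"
            )

    @property
    def area(self) -> int:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


def _as_box(b) -> tuple[int, int, int, int]:
    if isinstance(b, BoundingBox):
        return (b.x_min, b.y_min, b.x_max, b.y_max)
    return tuple(b)


def iou(a, b) -> float:
    """Intersection-over-union of two half-open boxes; symmetric, in [0, 1]."""
    ax0, ay0, ax1, ay1 = _as_box(a)
    bx0, by0, bx1, by1 = _as_box(b)
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def match_greedy(
    predictions: pd.DataFrame,
    truths: pd.DataFrame,
    iou_threshold: float = 0.5,
) -> tuple[list[bool], int]:
    """Greedy score-ordered matching of predictions to ground-truth boxes.

    Predictions (one class) are processed in descending score, ties broken
    by stable input order; each is a true positive iff its best-IoU
    *unmatched* truth on the same frame reaches ``iou_threshold``.  Each
    truth matches at most once.

    Returns the TP/FP flag per prediction (in the ranked order) and the
    number of truths left unmatched.
    """
    order = np.argsort(-predictions["score"].to_numpy(), kind="stable")
    truth_by_frame: dict[int, list] = {}
    for _, r in truths.iterrows():
        truth_by_frame.setdefault(int(r["frame"]), []).append(
            [(int(r["x_min"]), int(r["y_min"]), int(r["x_max"]), int(r["y_max"])), False]
        )
    flags: list[bool] = []
    for idx in order:
        r = predictions.iloc[int(idx)]
        box = (int(r["x_min"]), int(r["y_min"]), int(r["x_max"]), int(r["y_max"]))
        best, best_iou = None, 0.0
        for entry in truth_by_frame.get(int(r["frame"]), []):
            if entry[1]:
                continue
            v = iou(box, entry[0])
            if v > best_iou:
                best, best_iou = entry, v
        if best is not None and best_iou >= iou_threshold:
            best[1] = True
            flags.append(True)
        else:
            flags.append(False)
    unmatched = sum(
        1 for lst in truth_by_frame.values() for e in lst if not e[1]
    )
    return flags, unmatched


def precision_recall_curve(
    predictions: pd.DataFrame, truths: pd.DataFrame, iou_threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative precision/recall along the score-ranked prediction list."""
    n_truth = len(truths)
    if n_truth == 0:
        raise ValueError("precision-recall undefined with zero ground-truth boxes")
    flags, _ = match_greedy(predictions, truths, iou_threshold)
    tp = np.cumsum(np.asarray(flags, dtype=float))
    fp = np.cumsum(~np.asarray(flags, dtype=bool))
    recall = tp / n_truth
    precision = tp / np.maximum(tp + fp, 1e-12)
    return precision, recall


def average_precision(
    predictions: pd.DataFrame, truths: pd.DataFrame, iou_threshold: float = 0.5
) -> float:
    """All-point interpolated area under the precision-recall curve.

    The precision envelope ``p(r) = max{precision at recall >= r}`` is
    integrated over recall.  Requires at least one ground-truth box.
    """
    if len(predictions) == 0:
        return 0.0
    precision, recall = precision_recall_curve(predictions, truths, iou_threshold)
    mrec = np.concatenate(([0.0], recall, [recall[-1]]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    return float(np.sum(np.diff(mrec) * mpre[1:]))


def mean_average_precision(per_class_ap: dict[str, float]) -> float:
    """Arithmetic mean of per-class APs over evaluated classes."""
    if not per_class_ap:
        raise ValueError("no evaluable class: cannot compute mAP")
    return float(np.mean(list(per_class_ap.values())))


@dataclass
class DetectionEvalResult:
    """Per-class AP, mAP and precision-recall points at one IoU threshold."""

    per_class_ap: dict[str, float]
    map: float
    pr_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    iou_threshold: float
    skipped_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "iou_threshold": self.iou_threshold,
            "per_class_ap": {k: float(v) for k, v in self.per_class_ap.items()},
            "mAP": float(self.map),
            "skipped_classes": list(self.skipped_classes),
            "pr_curves": {
                k: {"precision": p.tolist(), "recall": r.tolist()}
                for k, (p, r) in self.pr_curves.items()
            },
        }


def evaluate_detections(
    predictions: pd.DataFrame,
    truths: pd.DataFrame,
    iou_threshold: float = 0.5,
) -> DetectionEvalResult:
    """Evaluate a prediction table against a ground-truth table.

    Classes with zero ground truth are excluded from mAP (their recall is
    undefined) and reported in ``skipped_classes``.
    """
    aps: dict[str, float] = {}
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    skipped: list[str] = []
    for cls in STRUCTURE_CLASSES:
        t = truths[truths["label"] == cls]
        p = predictions[predictions["label"] == cls]
        if len(t) == 0:
            if len(p) > 0:
                skipped.append(cls)
            continue
        aps[cls] = average_precision(p, t, iou_threshold)
        if len(p) > 0:
            curves[cls] = precision_recall_curve(p, t, iou_threshold)
    return DetectionEvalResult(
        per_class_ap=aps,
        map=mean_average_precision(aps),
        pr_curves=curves,
        iou_threshold=iou_threshold,
        skipped_classes=skipped,
    )


def reference_detect(
    stack: FrameStack,
    confidence_threshold: float = 0.0,
    bin_threshold: float = 45.0,
    min_area: int = 9,
) -> pd.DataFrame:
    """Deterministic template-layout detector for phantom renderings.

    Per frame: the per-pixel maximum over the stack serves as the
    background estimate; the background-subtracted contrast depth is
    thresholded at ``bin_threshold`` gray levels, 8-connected dark
    components of at least ``min_area`` pixels become boxes, each assigned
    to the structure class whose canonical layout anchor is nearest to the
    component centroid.  The score is the component's mean contrast depth
    normalized by the full rendering depth, clipped to [0, 1]; components
    nearest the nidus anchor are not one of the five reportable structure
    classes and are discarded.  Rows with score below
    ``confidence_threshold`` are dropped.

    On stacks that were not rendered with the canonical phantom layout the
    output is format-valid but untrusted.
    """
    anchors = layout_anchors(stack.frame_shape, with_nidus=True)
    names = list(anchors)
    anchor_arr = np.array([anchors[n] for n in names])
    background = stack.frames.max(axis=0).astype(float)
    structure8 = np.ones((3, 3), bool)

    rows: list[tuple] = []
    for f in range(stack.n_frames):
        depth = background - stack.frames[f].astype(float)
        mask = depth > bin_threshold
        labels, n_comp = ndimage.label(mask, structure=structure8)
        if n_comp == 0:
            continue
        for comp in range(1, n_comp + 1):
            comp_mask = labels == comp
            area = int(comp_mask.sum())
            if area < min_area:
                continue
            cy, cx = ndimage.center_of_mass(comp_mask)
            d2 = np.sum((anchor_arr - np.array([cy, cx])) ** 2, axis=1)
            cls = names[int(np.argmin(d2))]
            if cls == "nidus":
                continue
            score = float(np.clip(depth[comp_mask].mean() / CONTRAST_DEPTH, 0.0, 1.0))
            if score < confidence_threshold:
                continue
            ys, xs = np.nonzero(comp_mask)
            rows.append(
                (stack.case_id, f, cls,
                 int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1,
                 score)
            )
    return new_detection_table(rows)
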