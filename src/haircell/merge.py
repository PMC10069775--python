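"""Merging tile-local detections into one global cell set.

Tiles overlap by design, so one physical cell is often detected several
times. Merging is: (1) confidence rejection, (2) greedy class-agnostic
non-maximum suppression at a box-overlap (IoU) threshold of 0.30 by
default, and optionally (3) removal of detections lying too far from the
estimated cochlear path (whole-coil analyses only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InputError

DEFAULT_NMS_IOU = 0.30
DEFAULT_PATH_DISTANCE_UM = 40.0


@dataclass
class MergeConfig:
    score_threshold: float = 0.3
    nms_iou_threshold: float = DEFAULT_NMS_IOU
    max_path_distance_um: Optional[float] = None  # None disables the filter

    def __post_init__(self):
        for name in ("score_threshold", "nms_iou_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]; got {v}")
        if self.max_path_distance_um is not None and self.max_path_distance_um <= 0:
            raise ConfigurationError("max_path_distance_um must be positive or None")


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (row0, col0, row1, col1) boxes."""
    ar0, ac0, ar1, ac1 = box_a
    br0, bc0, br1, bc1 = box_b
    area_a = (ar1 - ar0) * (ac1 - ac0)
    area_b = (br1 - br0) * (bc1 - bc0)
    if area_a <= 0 or area_b <= 0:
        raise InputError("degenerate (zero-area) box")
    ih = min(ar1, br1) - max(ar0, br0)
    iw = min(ac1, bc1) - max(ac0, bc0)
    if ih <= 0 or iw <= 0:
        return 0.0
    inter = ih * iw
    return inter / (area_a + area_b - inter)


def _iou_matrix_one_vs_many(box: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Vectorized IoU of one box against an (N, 4) array."""
    ih = np.minimum(box[2], boxes[:, 2]) - np.maximum(box[0], boxes[:, 0])
    iw = np.minimum(box[3], boxes[:, 3]) - np.maximum(box[1], boxes[:, 1])
    inter = np.clip(ih, 0, None) * np.clip(iw, 0, None)
    area = (box[2] - box[0]) * (box[3] - box[1])
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    return inter / (area + areas - inter)


def reject_by_score(dets: list, threshold: float) -> list:
    """Keep detections with score >= threshold, preserving order."""
    if not (0.0 <= threshold <= 1.0):
        raise InputError(f"threshold must be in [0, 1]; got {threshold}")
    return [d for d in dets if d.score >= threshold]


def nms(dets: list, iou_threshold: float = DEFAULT_NMS_IOU) -> list:
    """Greedy class-agnostic non-maximum suppression.

    Detections are visited in descending score order (ties keep the earlier
    detection in input order); one is kept iff its IoU with every
    already-kept detection stays below *iou_threshold*. Class-agnostic so
    that cross-tile duplicates of one physical cell — occasionally assigned
    different classes — survive exactly once.
    """
    if not dets:
        return []
    boxes = np.array([d.box for d in dets], dtype=np.float64)
    scores = np.array([d.score for d in dets], dtype=np.float64)
    # stable sort on -score: equal scores retain input order
    order = np.argsort(-scores, kind="stable")
    kept_idx: list = []
    kept_boxes = np.empty((0, 4), dtype=np.float64)
    for i in order:
        if kept_idx:
            overlaps = _iou_matrix_one_vs_many(boxes[i], kept_boxes)
            if (overlaps >= iou_threshold).any():
                continue
        kept_idx.append(int(i))
        kept_boxes = np.vstack([kept_boxes, boxes[i]])
    kept_idx.sort()  # report survivors in input order
    return [dets[i] for i in kept_idx]


def merge_detections(dets: list, config: MergeConfig, path=None) -> list:
    """Full merge: confidence rejection, NMS, optional path-distance filter."""
    out = reject_by_score(dets, config.score_threshold)
    out = nms(out, config.nms_iou_threshold)
    if config.max_path_distance_um is not None and path is not None:
        out = filter_by_path_distance(out, path, config.max_path_distance_um)
    return out


def filter_by_path_distance(dets: list, path, max_um: float) -> list:
    """Drop detections whose centroid lies more than *max_um* from the path.

    Distance is the perpendicular (point-to-polyline) distance in microns.
    Only meaningful for whole-coil analyses with a finalized path.
    """
    if max_um <= 0:
        raise InputError(f"max_um must be positive; got {max_um}")
    if path is None or len(path.points) < 2:
        raise ConfigurationError("path-distance filtering requires a finalized cochlear path")
    from .path_estimation import project_cells

    projected = project_cells(dets, path)
    return [d for d, _pct, dist in projected if dist <= max_um]
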