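"""Confidence/NMS threshold optimization.

Raw (unthresholded) detections from annotated samples are swept over a
grid of (confidence threshold, NMS IoU threshold) pairs — 100 steps per
axis from 0 to 1 by default. At each grid cell the thresholds are applied,
survivors are matched to ground truth, and an accuracy metric
``TP - FN - FP`` (true positives penalized by misses and false alarms;
detection has no meaningful true-negative count) is averaged over samples.
The argmax pair becomes the recommended default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import InputError
from .merge import iou, nms, reject_by_score

DEFAULT_STEPS = 100
DEFAULT_MATCH_IOU = 0.5


@dataclass
class MatchResult:
    """Greedy one-to-one prediction/truth matching."""

    tp: int
    fp: int
    fn: int
    pairs: list  # (pred index, truth index, IoU)


def match_detections(preds: list, truths: list, min_iou: float = DEFAULT_MATCH_IOU) -> MatchResult:
    """Match predictions to ground truth, class-aware, greedy by score.

    Predictions are visited in descending score order; each claims the
    still-unclaimed truth of its own class with the highest IoU >= min_iou.
    Unclaimed predictions are false positives, unclaimed truths false
    negatives.
    """
    if not (0 < min_iou <= 1):
        raise InputError("min_iou must lie in (0, 1]")
    order = np.argsort(-np.array([p.score for p in preds]), kind="stable") if preds else []
    claimed = set()
    pairs = []
    for pi in order:
        pred = preds[pi]
        best_iou, best_ti = 0.0, None
        for ti, truth in enumerate(truths):
            if ti in claimed or truth.label != pred.label:
                continue
            o = iou(pred.box, truth.box)
            if o >= min_iou and o > best_iou:
                best_iou, best_ti = o, ti
        if best_ti is not None:
            claimed.add(best_ti)
            pairs.append((int(pi), best_ti, best_iou))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(preds) - tp, fn=len(truths) - tp, pairs=pairs)


def default_metric(match: MatchResult) -> float:
    """TP - FN - FP: hits penalized by misses and false alarms."""
    return match.tp - match.fn - match.fp


@dataclass
class GridSearchResult:
    score_grid: np.ndarray
    nms_grid: np.ndarray
    accuracy_surface: np.ndarray  # (len(score_grid), len(nms_grid))
    best_score_threshold: float
    best_nms_threshold: float
    best_indices: tuple = field(default=(0, 0))


def grid_search(
    raw_preds_per_sample: list,
    truths_per_sample: list,
    steps: int = DEFAULT_STEPS,
    min_iou: float = DEFAULT_MATCH_IOU,
    metric: Callable = default_metric,
) -> GridSearchResult:
    """Exhaustive accuracy surface over the threshold grid.

    Ties in the surface maximum break toward the larger score threshold,
    then the larger NMS threshold. Deterministic given inputs.
    """
    if not raw_preds_per_sample:
        raise InputError("grid search needs at least one sample")
    if len(raw_preds_per_sample) != len(truths_per_sample):
        raise InputError("predictions and truths must pair one-to-one per sample")
    if steps < 2:
        raise InputError("steps must be >= 2")
    score_grid = np.linspace(0.0, 1.0, steps)
    nms_grid = np.linspace(0.0, 1.0, steps)
    surface = np.zeros((steps, steps), dtype=np.float64)
    for preds, truths in zip(raw_preds_per_sample, truths_per_sample):
        for i, st in enumerate(score_grid):
            kept_score = reject_by_score(preds, st)
            for j, nt in enumerate(nms_grid):
                survivors = nms(kept_score, nt)
                surface[i, j] += metric(match_detections(survivors, truths, min_iou=min_iou))
    surface /= len(raw_preds_per_sample)

    best = surface.max()
    ties = np.argwhere(surface == best)
    # prefer the largest score threshold, then the largest NMS threshold
    bi, bj = max(map(tuple, ties))
    return GridSearchResult(
        score_grid=score_grid,
        nms_grid=nms_grid,
        accuracy_surface=surface,
        best_score_threshold=float(score_grid[bi]),
        best_nms_threshold=float(nms_grid[bj]),
        best_indices=(int(bi), int(bj)),
    )


def accuracy_curves(result: GridSearchResult) -> tuple:
    """Surface slices through the argmax: (profile over score thresholds at
    the best NMS threshold, profile over NMS thresholds at the best score
    threshold)."""
    bi, bj = result.best_indices
    return result.accuracy_surface[:, bj].copy(), result.accuracy_surface[bi, :].copy()
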