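"""Object-level detection and classification metrics.

Detection is scored at the object level (a segmented nucleus either matches a
true nucleus or it does not); there is deliberately no voxel-overlap (IoU)
scoring.  Reporting conventions: recall/precision/F-measure rounded to three
decimals; overall classification accuracy truncated (floored) to two
decimals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LabelVolume
from .network import CompositionTable

__all__ = [
    "DetectionCounts",
    "detection_metrics",
    "confusion_accuracy",
    "composition_percentages",
    "match_objects",
]

CLASS_ORDER = ("alpha", "beta", "delta", "unlabeled")


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def detection_metrics(c: DetectionCounts) -> tuple[float, float, float]:
    """(recall %, precision %, F-measure %), each rounded to 3 decimals.

    recall = 100 TP/(TP+FN); precision = 100 TP/(TP+FP); F is their harmonic
    mean.  Zero denominators yield 0 with a warning.
    """
    if c.tp + c.fn == 0 or c.tp + c.fp == 0:
        warnings.warn("degenerate detection counts; metrics reported as 0")
        recall = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
        precision = 100.0 * c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
        f = 0.0
        return (round(recall, 3), round(precision, 3), round(f, 3))
    recall = 100.0 * c.tp / (c.tp + c.fn)
    precision = 100.0 * c.tp / (c.tp + c.fp)
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return (round(recall, 3), round(precision, 3), round(f, 3))


def confusion_accuracy(m: np.ndarray | pd.DataFrame) -> float:
    """Overall accuracy % = 100 * trace / total, truncated to 2 decimals
    (printed convention of the reference tables)."""
    arr = np.asarray(m, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.size == 0:
        raise ValueError("confusion matrix must be square and nonempty")
    if arr.min() < 0:
        raise ValueError("confusion matrix entries must be >= 0")
    total = arr.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * np.trace(arr) / total
    return math.floor(acc * 100 + 1e-9) / 100


def composition_percentages(counts: dict[str, int]) -> CompositionTable:
    """CompositionTable from per-type cell counts; unlabeled cells are
    excluded from the denominator (percentages via ``.percentages``)."""
    return CompositionTable({t: counts.get(t, 0) for t in ("alpha", "beta", "delta")})


def match_objects(predicted: LabelVolume, truth: pd.DataFrame) -> DetectionCounts:
    """Object-level matching of a predicted label image against ground truth.

    A predicted label is a true positive if its centroid falls inside a true
    nucleus (sphere of ``radius_um`` around the truth centroid, in calibrated
    space) that no earlier prediction has claimed; predictions are visited in
    ascending label order and claim the nearest containing truth.  Unclaimed
    predictions are false positives, unclaimed truths false negatives.
    """
    need = {"x_um", "y_um", "z_um", "radius_um"}
    if not need <= set(truth.columns):
        raise ValueError(f"truth table needs columns {sorted(need)}")
    cal = predicted.calibration
    lab = predicted.values
    t_pos = truth[["x_um", "y_um", "z_um"]].to_numpy(float)
    t_rad = truth["radius_um"].to_numpy(float)
    claimed = np.zeros(len(truth), dtype=bool)
    tp = fp = 0
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if len(ids):
        from scipy import ndimage

        cents = ndimage.center_of_mass(np.ones_like(lab), lab, ids)
        for cent in cents:
            p = np.array(cent) * [cal.dx, cal.dy, cal.dz]
            d = np.linalg.norm(t_pos - p, axis=1)
            inside = np.flatnonzero((d <= t_rad) & ~claimed)
            if len(inside):
                pick = inside[np.argmin(d[inside])]
                claimed[pick] = True
                tp += 1
            else:
                fp += 1
    fn = int((~claimed).sum())
    return DetectionCounts(tp, fp, fn)
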