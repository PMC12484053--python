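"""Instance-mask geometry and detection-evaluation utilities.

Pixel perimeters are measured on the 0.5 iso-level of the (binary or
probability) mask, traced marching-squares style, which gives stable
sub-pixel contours even for seedlings only a few pixels wide. The perimeter
is the Euclidean length of the closed vertex cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

__all__ = [
    "ContourPolygon",
    "DetectionEvalSet",
    "binarize_and_merge",
    "extract_contour",
    "perimeter",
    "mask_iou",
    "average_precision",
    "mask_centroid",
]

logger = logging.getLogger(__name__)

COCO_THRESHOLDS = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


@dataclass(frozen=True)
class ContourPolygon:
    """Closed polygon traced around one instance.

    ``vertices`` is an (n, 2) float array of (x, y) points in pixel
    coordinates, ordered around the boundary; the closing edge from the last
    vertex back to the first is implied.
    """

    vertices: np.ndarray
    instance_id: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a contour polygon needs at least 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("contour vertices must be finite")
        object.__setattr__(self, "vertices", v)


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask, dtype=float)
    if arr.ndim != 2:
        raise ValueError("masks must be 2-D")
    if not np.all(np.isfinite(arr)):
        raise ValueError("mask values must be finite")
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("mask values must lie in [0, 1]")
    return arr


def binarize_and_merge(masks, threshold: float = 0.5, shape=None) -> np.ndarray:
    """Binarize each probability mask and merge them into one binary map.

    Each mask is thresholded (``value > threshold``), the binary maps are
    summed, and the sum is clipped back to {0, 1} so overlapping instances do
    not overflow the valid range. An empty list yields the all-zero map
    (``shape`` must then be given).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    masks = list(masks)
    if not masks:
        if shape is None:
            raise ValueError("empty mask list needs an explicit shape")
        return np.zeros(shape, dtype=np.uint8)
    shape = np.asarray(masks[0]).shape
    total = np.zeros(shape, dtype=np.int64)
    for m in masks:
        arr = _validate_mask(m)
        if arr.shape != shape:
            raise ValueError(f"mask shape {arr.shape} does not match {shape}")
        total += (arr > threshold).astype(np.int64)
    return np.clip(total, 0, 1).astype(np.uint8)


def extract_contour(mask: np.ndarray, instance_id: int = 0) -> ContourPolygon:
    """Trace the 0.5 iso-level boundary of the largest connected component.

    Works on binary masks (the contour then runs midway between foreground
    and background pixel centres) and on floating-point probability masks,
    where the 0.5 level is interpolated sub-pixel — the preferred input for
    perimeter work, since it avoids the staircase bias of hard binarization.

    The mask is zero-padded by one pixel so components touching the frame
    border still produce closed contours; coordinates are shifted back to the
    original pixel grid afterwards. Holes are ignored (outer contour only);
    if several components are present the largest is kept.
    """
    arr = np.asarray(mask)
    values = arr.astype(float) if arr.dtype == bool else _validate_mask(arr)
    fg = values > 0.5
    if not fg.any():
        raise ValueError("no foreground pixels in mask")
    labels, n_comp = measure.label(fg, connectivity=2, return_num=True)
    if n_comp > 1:
        logger.info("instance %s has %d components; keeping largest", instance_id, n_comp)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        keep = labels == int(np.argmax(sizes))
        values = np.where(keep, values, 0.0)
    padded = np.pad(values, 1)
    contours = measure.find_contours(padded, 0.5)
    # The outer boundary is the longest closed contour of the component.
    best = max(contours, key=_vertex_walk_length)
    verts = best[:-1] if np.allclose(best[0], best[-1]) else best
    # find_contours returns (row, col); convert to (x, y) and undo padding.
    xy = np.stack([verts[:, 1] - 1.0, verts[:, 0] - 1.0], axis=1)
    return ContourPolygon(vertices=xy, instance_id=instance_id)


def _vertex_walk_length(vertices: np.ndarray) -> float:
    closed = np.vstack([vertices, vertices[:1]])
    return float(np.hypot(np.diff(closed[:, 0]), np.diff(closed[:, 1])).sum())


def perimeter(polygon) -> float:
    """Euclidean length of the closed vertex cycle, in pixels."""
    verts = polygon.vertices if isinstance(polygon, ContourPolygon) else np.asarray(polygon, float)
    if verts.ndim != 2 or verts.shape[0] < 3:
        raise ValueError("perimeter needs a polygon with at least 3 vertices")
    return _vertex_walk_length(verts)


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Foreground centroid as (x, y) in pixel coordinates."""
    arr = np.asarray(mask)
    if arr.dtype != bool:
        arr = arr > 0.5
    if not arr.any():
        raise ValueError("no foreground pixels in mask")
    rows, cols = np.nonzero(arr)
    return float(cols.mean()), float(rows.mean())


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks of equal shape."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one shape")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU undefined: both masks are empty")
    inter = np.logical_and(a, b).sum()
    return float(inter) / float(union)


@dataclass
class DetectionEvalSet:
    """Predicted and ground-truth instance masks for AP evaluation."""

    predictions: list = field(default_factory=list)  # (mask, confidence) pairs
    ground_truths: list = field(default_factory=list)  # masks
    iou_thresholds: tuple = COCO_THRESHOLDS

    def __post_init__(self) -> None:
        if not self.ground_truths:
            raise ValueError("need at least one ground-truth instance")
        for _, conf in self.predictions:
            if not 0 <= conf <= 1:
                raise ValueError("confidences must lie in [0, 1]")
        for thr in self.iou_thresholds:
            if not 0 < thr < 1:
                raise ValueError("IoU thresholds must lie in (0, 1)")


def _ap_at_threshold(iou_matrix: np.ndarray, order: np.ndarray, thr: float) -> float:
    """AP with greedy confidence-ordered matching and all-point interpolation."""
    n_pred, n_gt = iou_matrix.shape
    matched = np.zeros(n_gt, dtype=bool)
    tp = np.zeros(n_pred)
    for rank, p in enumerate(order):
        ious = np.where(matched, -1.0, iou_matrix[p])
        best = int(np.argmax(ious)) if n_gt else -1
        if n_gt and ious[best] >= thr:
            matched[best] = True
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    prec = cum_tp / (np.arange(n_pred) + 1.0)
    rec = cum_tp / n_gt
    # precision envelope + sum over recall steps (COCO-style all-point AP)
    prec_env = np.maximum.accumulate(prec[::-1])[::-1]
    rec_prev = np.concatenate([[0.0], rec[:-1]])
    return float(np.sum((rec - rec_prev) * prec_env))


def average_precision(eval_set: DetectionEvalSet) -> dict:
    """COCO-style mask AP at 0.5 and averaged over 0.5:0.05:0.95.

    Returns a dict with ``ap_per_threshold``, ``map50`` and ``map50_95``.
    """
    n_pred = len(eval_set.predictions)
    if n_pred == 0:
        logger.warning("no predictions supplied; AP is 0 at every threshold")
        zeros = {float(t): 0.0 for t in eval_set.iou_thresholds}
        return {"ap_per_threshold": zeros, "map50": 0.0, "map50_95": 0.0}
    confs = np.array([c for _, c in eval_set.predictions], dtype=float)
    order = np.argsort(-confs, kind="stable")
    iou_matrix = np.zeros((n_pred, len(eval_set.ground_truths)))
    for i, (pm, _) in enumerate(eval_set.predictions):
        for j, gm in enumerate(eval_set.ground_truths):
            pa = np.asarray(pm).astype(bool)
            ga = np.asarray(gm).astype(bool)
            if pa.any() or ga.any():
                iou_matrix[i, j] = mask_iou(pa, ga)
    per_thr = {
        float(t): _ap_at_threshold(iou_matrix, order, float(t))
        for t in eval_set.iou_thresholds
    }
    aps = list(per_thr.values())
    map50 = per_thr.get(0.5, aps[0])
    return {
        "ap_per_threshold": per_thr,
        "map50": map50,
        "map50_95": float(np.mean(aps)),
    }
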