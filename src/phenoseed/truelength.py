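"""Pixel perimeter to physical seedling length.

Converts raw mask perimeters into physical lengths in four fixed steps:
ring-stratified lens-distortion correction (calibrated empirically, never
from a known distortion coefficient), halving of the closed-contour
perimeter (a thin seedling's outline runs up one side and down the other),
phototropic tilt de-foreshortening, and the pixel-to-cm scale of the box.

The distortion corrector is a step function of radial distance: seedlings
are stratified into concentric rings around the calibration point and each
ring carries one multiplicative factor mapping an observed perimeter to its
centre-equivalent value, estimated from repeated captures of the same
physical seedlings at different radii.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SceneConfig
from .masks import extract_contour, mask_centroid, perimeter

__all__ = [
    "CalibrationModel",
    "fit_ring_calibration",
    "correct_perimeter",
    "smooth_angle",
    "rotate_align",
    "tilt_factor",
    "age_filter",
    "true_length",
    "agreement_slope",
    "measure_scene",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Per-ring perimeter correction factors anchored at the centre.

    ``ring_edges_px`` are the outer radial boundaries of the rings (strictly
    increasing); ``ring_ratio[i]`` multiplies perimeters observed in ring
    ``i`` to map them to their centre-equivalent value. The innermost ratio
    is 1 by construction; for a pincushion lens outer rings over-measure, so
    their ratios are below 1.
    """

    center_px: tuple[float, float]
    ring_edges_px: np.ndarray
    ring_ratio: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.ring_edges_px, dtype=float)
        ratios = np.asarray(self.ring_ratio, dtype=float)
        if edges.ndim != 1 or edges.size != ratios.size:
            raise ValueError("ring_edges_px and ring_ratio must have equal length")
        if np.any(np.diff(edges) <= 0) or edges[0] <= 0:
            raise ValueError("ring_edges_px must be positive and strictly increasing")
        if ratios[0] != 1.0:
            raise ValueError("innermost ring ratio must be 1 by construction")
        if np.any(ratios <= 0):
            raise ValueError("ring ratios must be positive")
        object.__setattr__(self, "ring_edges_px", edges)
        object.__setattr__(self, "ring_ratio", ratios)
        object.__setattr__(self, "n_obs", np.asarray(self.n_obs, dtype=int))

    @property
    def n_rings(self) -> int:
        return int(self.ring_edges_px.size)

    def ring_of(self, radial_px: float) -> int:
        """Index of the ring containing a radial distance (outermost beyond)."""
        idx = int(np.searchsorted(self.ring_edges_px, radial_px, side="left"))
        if idx >= self.n_rings:
            warnings.warn(
                f"radial distance {radial_px:.1f} px beyond outermost ring edge; "
                "using outermost ratio",
                stacklevel=2,
            )
            idx = self.n_rings - 1
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ring": np.arange(self.n_rings),
                "outer_edge_px": self.ring_edges_px,
                "ratio": self.ring_ratio,
                "n_obs": self.n_obs,
            }
        )


def fit_ring_calibration(
    observations: pd.DataFrame,
    n_rings: int = 3,
    center_px: tuple[float, float] = (0.0, 0.0),
    ring_edges_px=None,
    stratify: str = "anchored",
    anchor_frac: float = 0.07,
) -> CalibrationModel:
    """Fit per-ring correction factors from repeated-capture observations.

    ``observations`` needs columns ``seedling_id``, ``radial_px`` and
    ``observed_perimeter_px``. For every physical seedling the mean
    perimeter observed in the innermost ring is divided by its mean
    perimeter in each ring; the per-ring factor is the median of these
    quotients across seedlings (robust to the odd bad mask). Seedlings never
    observed in the innermost ring carry no anchor and are dropped with a
    warning.

    Ring boundaries default to ``stratify='anchored'``: the innermost ring
    is a narrow disc of radius ``anchor_frac`` times the observed radial
    span around the calibration point — its ratio is pinned at 1, so it must
    only contain captures that are effectively undistorted — and the
    remaining annulus is split into rings of equal area (equal width in
    squared radius). Since the radial warp grows with squared radius,
    equal-area rings spread the within-ring warp variation evenly across
    rings. ``stratify='equal-width'`` gives fixed-width rings over the
    observed span instead. Explicit ``ring_edges_px`` (outer boundaries,
    increasing) override both.
    """
    req = {"seedling_id", "radial_px", "observed_perimeter_px"}
    missing = req - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns {sorted(missing)}")
    obs = observations.copy()
    if ring_edges_px is None:
        radial = obs["radial_px"].to_numpy(dtype=float)
        r_max = float(radial.max())
        if r_max <= 0:
            raise ValueError("all observations at zero radius; cannot stratify")
        if stratify == "anchored":
            anchor = anchor_frac * r_max
            if not (radial > anchor).any():
                raise ValueError("no observations beyond the anchor ring")
            upper = np.sqrt(np.linspace(anchor**2, r_max**2, n_rings))[1:]
            ring_edges_px = np.concatenate([[anchor], upper])
        elif stratify == "equal-width":
            ring_edges_px = np.linspace(0.0, r_max, n_rings + 1)[1:]
        else:
            raise ValueError("stratify must be 'anchored' or 'equal-width'")
    edges = np.asarray(ring_edges_px, dtype=float)
    obs["ring"] = np.minimum(
        np.searchsorted(edges, obs["radial_px"].to_numpy(), side="left"),
        edges.size - 1,
    )
    counts = obs.groupby("ring").size().reindex(range(edges.size), fill_value=0)
    for ring, cnt in counts.items():
        if cnt == 0:
            raise ValueError(f"ring {ring} has no calibration observations")

    inner_mean = (
        obs[obs["ring"] == 0].groupby("seedling_id")["observed_perimeter_px"].mean()
    )
    anchored = set(inner_mean.index)
    dropped = sorted(set(obs["seedling_id"]) - anchored)
    if dropped:
        warnings.warn(
            f"seedlings {dropped} never observed in the innermost ring; excluded",
            stacklevel=2,
        )
        obs = obs[obs["seedling_id"].isin(anchored)]

    ratios = np.ones(edges.size)
    for ring in range(1, edges.size):
        ring_mean = (
            obs[obs["ring"] == ring].groupby("seedling_id")["observed_perimeter_px"].mean()
        )
        quotients = (inner_mean / ring_mean).dropna()
        if quotients.empty:
            raise ValueError(f"ring {ring} has no observations from anchored seedlings")
        ratios[ring] = float(quotients.median())
    return CalibrationModel(
        center_px=tuple(float(c) for c in center_px),
        ring_edges_px=edges,
        ring_ratio=ratios,
        n_obs=counts.to_numpy(),
    )


def correct_perimeter(perimeter_px: float, centroid_px, model: CalibrationModel) -> float:
    """Map an observed perimeter to its centre-equivalent value."""
    if perimeter_px < 0:
        raise ValueError("perimeter must be non-negative")
    cx, cy = model.center_px
    x, y = float(centroid_px[0]), float(centroid_px[1])
    radial = math.hypot(x - cx, y - cy)
    return perimeter_px * float(model.ring_ratio[model.ring_of(radial)])


def _wrap_deg(angle: float) -> float:
    """Wrap to (-180, 180]."""
    return (angle + 180.0) % 360.0 - 180.0


def smooth_angle(
    raw_azimuth_deg: float,
    priors=(45.0, 135.0, 225.0, 315.0),
    lam: float = 0.5,
    tolerance_deg: float = 15.0,
) -> float:
    """Shrink a detector azimuth toward the nearest lighting prior.

    Angles within the +-``tolerance_deg`` band of their nearest prior are
    physically plausible phototropic leans and pass unshrunk; outside the
    band the angle is pulled toward the prior by weight ``lam`` along the
    shorter arc of the circle.
    """
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0, 1]")
    priors = tuple(priors)
    if not priors:
        warnings.warn("empty prior set; returning raw angle", stacklevel=2)
        return raw_azimuth_deg % 360.0
    raw = raw_azimuth_deg % 360.0
    deltas = [_wrap_deg(p - raw) for p in priors]
    delta = min(deltas, key=abs)
    if abs(delta) <= tolerance_deg:
        return raw
    return (raw + lam * delta) % 360.0


def rotate_align(points, theta_deg: float, origin=None):
    """Rotate points by ``theta_deg`` (clockwise in image coordinates).

    By default the rotation is about the point-set centroid, which aligns an
    instance's principal axis with the vertical when ``theta_deg`` is its
    smoothed lean azimuth. A pure rotation, so all pairwise distances are
    preserved.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates rejected")
    o = pts.mean(axis=0) if origin is None else np.asarray(origin, dtype=float)
    th = math.radians(theta_deg)
    # y grows downward, so this matrix rotates image content clockwise
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    out = (pts - o) @ rot.T + o
    return out if np.asarray(points).ndim == 2 else out[0]


def tilt_factor(tilt_deg: float, clamp: tuple[float, float] = (30.0, 60.0)) -> float:
    """De-foreshortening multiplier ``1 / sin(tilt)`` with a lower clamp.

    ``tilt_deg`` is measured from the vertical axis: 90 deg lies fully in the
    image plane (factor exactly 1). Tilts below ``clamp[0]`` are clamped
    before inversion so near-vertical seedlings cannot be amplified without
    bound; the upper clamp value marks the top of the trusted lighting-angle
    band and is validated but does not cap the tilt (larger tilts need less
    correction, not more).
    """
    if not 0 <= tilt_deg <= 90:
        raise ValueError("tilt_deg must lie in [0, 90]")
    lo, hi = clamp
    if not 0 < lo <= hi <= 90:
        raise ValueError("clamp must satisfy 0 < lo <= hi <= 90")
    eff = max(tilt_deg, lo)
    return 1.0 / math.sin(math.radians(eff))


def age_filter(
    instances: pd.DataFrame,
    cutoff_age_h: float = 60.0,
    young_threshold: float = 0.4,
    old_threshold: float = 0.6,
) -> pd.DataFrame:
    """Age-dependent confidence filter.

    Young seedlings (tillering, ``age_h < cutoff``) are kept from confidence
    0.4 up so weak seedlings survive; older ones (jointing) need 0.6 to
    filter noise detections.
    """
    conf = instances["confidence"].to_numpy(dtype=float)
    if conf.size and (conf.min() < 0 or conf.max() > 1):
        raise ValueError("confidences must lie in [0, 1]")
    young = instances["age_h"].to_numpy(dtype=float) < cutoff_age_h
    keep = np.where(young, conf >= young_threshold, conf >= old_threshold)
    return instances[keep].reset_index(drop=True)


def true_length(
    perimeter_px: float,
    centroid_px,
    tilt_deg: float,
    model: CalibrationModel,
    config: SceneConfig,
    clamp: tuple[float, float] = (30.0, 60.0),
) -> float:
    """Physical seedling length in cm from a raw mask perimeter.

    Composition order is fixed: distortion correction, halving, tilt
    de-foreshortening, pixel-to-cm scaling.
    """
    corrected = correct_perimeter(perimeter_px, centroid_px, model)
    length_px = corrected / 2.0
    length_px *= tilt_factor(tilt_deg, clamp)
    return length_px * config.box_cm / config.frame_px


def agreement_slope(manual_cm, module_cm) -> tuple[float, float]:
    """OLS slope (and intercept) of module output on manual measurement."""
    x = np.asarray(manual_cm, dtype=float)
    y = np.asarray(module_cm, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 paired measurements")
    if np.ptp(x) == 0:
        raise ValueError("manual measurements are constant; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def measure_scene(
    scene,
    angles: pd.DataFrame,
    model: CalibrationModel,
    config: SceneConfig,
    clamp: tuple[float, float] = (30.0, 60.0),
    apply_correction: bool = True,
) -> pd.DataFrame:
    """Measure every instance of a scene.

    ``scene`` is either a uint label image (0 background) or a dict mapping
    instance id to ``(x0, y0, values)`` per-instance probability-mask
    patches; the soft form is preferred for perimeters because its 0.5
    iso-contour is traced sub-pixel. ``angles`` maps instance id to tilt
    (columns ``id`` and ``tilt_deg``); it is the per-instance orientation
    input an oriented-box detector would supply. Returns one row per
    instance with the raw perimeter, the distortion-corrected perimeter and
    the final physical length.
    """
    tilt_by_id = dict(zip(angles["id"], angles["tilt_deg"]))
    if isinstance(scene, dict):
        items = [
            (int(inst), offx, offy, window)
            for inst, (offx, offy, window) in sorted(scene.items())
        ]
    else:
        label_image = np.asarray(scene)
        ids = np.unique(label_image)
        items = [(int(i), 0, 0, label_image == i) for i in ids if i != 0]
    rows = []
    for inst, offx, offy, mask in items:
        contour = extract_contour(mask, instance_id=inst)
        perim = perimeter(contour)
        cx, cy = mask_centroid(mask)
        centroid = (cx + offx, cy + offy)
        tilt = float(tilt_by_id[inst])
        if apply_correction:
            corrected = correct_perimeter(perim, centroid, model)
        else:
            corrected = perim
        length_cm = (
            corrected / 2.0 * tilt_factor(tilt, clamp) * config.box_cm / config.frame_px
        )
        rows.append(
            {
                "id": inst,
                "perimeter_px": perim,
                "corrected_perimeter_px": corrected,
                "centroid_x_px": centroid[0],
                "centroid_y_px": centroid[1],
                "tilt_deg": tilt,
                "length_cm": length_cm,
            }
        )
    return pd.DataFrame(rows)
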