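"""Synthetic top-down seedling scenes with exact ground truth.

This module stands in for the camera plus neural segmenter: it renders
instance label images of a gridded germination box as the rig would see them
(phototropic lean, out-of-plane tilt foreshortening, pincushion distortion)
while keeping the exact midline geometry of every seedling, so downstream
measurement code can be scored against known truth.

Geometry conventions
--------------------
* Pixel coordinates: origin at the top-left, x right, y down, pixel centres
  at integer coordinates.
* Azimuth: compass direction of lean, clockwise from image-up, so NE, SE,
  SW, NW map to 45, 135, 225, 315 degrees.
* Tilt: angle from the vertical (optical) axis in [0, 90]; 90 deg means the
  seedling lies fully in the image plane. The top-down apparent length is
  ``true_length * sin(tilt)``.
* Distortion: single-term radial model ``p' = c + d * (1 + k1 * r**2)`` with
  ``d = p - c`` and ``r = |d|`` normalised by the half frame diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SceneConfig, TreatmentDesign
from .masks import extract_contour, mask_centroid, perimeter

__all__ = [
    "SeedlingGroundTruth",
    "apply_pincushion",
    "sample_seedlings",
    "generate_scene",
    "generate_calibration_set",
    "generate_growth_series",
    "stroke_probability_window",
    "rasterize_stroke",
    "bezier_midline",
    "GROUND_TRUTH_COLUMNS",
]

GROUND_TRUTH_COLUMNS = [
    "id",
    "row",
    "col",
    "true_length_cm",
    "azimuth_deg",
    "tilt_deg",
    "confidence",
    "age_h",
    "width_px",
    "centroid_x_px",
    "centroid_y_px",
]


def apply_pincushion(points, k1: float, center, half_diag_px: float | None = None):
    """Warp points with the single-coefficient radial pincushion model.

    Each point ``p`` maps to ``center + d * (1 + k1 * r**2)`` where
    ``d = p - center`` and ``r = |d| / half_diag_px``. With the default
    ``half_diag_px`` the centre is assumed to be the frame centre, so the
    normalisation length is ``|center|`` (the half frame diagonal).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[-1] != 2:
        raise ValueError("points must be (x, y) pairs")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates rejected")
    if k1 < 0:
        raise ValueError("k1 must be non-negative")
    c = np.asarray(center, dtype=float)
    if half_diag_px is None:
        half_diag_px = float(np.hypot(c[0], c[1]))
    d = pts - c
    r2 = (d * d).sum(axis=1) / (half_diag_px * half_diag_px)
    warped = c + d * (1.0 + k1 * r2)[:, None]
    return warped if np.asarray(points).ndim == 2 else warped[0]


@dataclass(frozen=True)
class SeedlingGroundTruth:
    """Exact geometry and detector attributes of one synthetic seedling.

    ``polyline_cm`` holds the midline in a local (perp, along) frame in cm
    with arc length exactly ``true_length_cm``; placement (cell, azimuth,
    tilt) positions it in the box at render time.
    """

    id: int
    cell: tuple[int, int]
    polyline_cm: np.ndarray
    true_length_cm: float
    width_px: float
    azimuth_deg: float
    tilt_deg: float
    confidence: float
    age_h: float

    def __post_init__(self) -> None:
        poly = np.asarray(self.polyline_cm, dtype=float)
        object.__setattr__(self, "polyline_cm", poly)
        arc = float(np.hypot(np.diff(poly[:, 0]), np.diff(poly[:, 1])).sum())
        if abs(arc - self.true_length_cm) > 1e-9:
            raise ValueError("true_length_cm must equal the polyline arc length")
        if not 0 <= self.tilt_deg <= 90:
            raise ValueError("tilt_deg must lie in [0, 90]")
        if not 0 <= self.confidence <= 1:
            raise ValueError("confidence must lie in [0, 1]")
        if self.width_px <= 0:
            raise ValueError("width_px must be positive")


def bezier_midline(length_cm: float, bend_frac: float = 0.0, n_vertices: int = 33) -> np.ndarray:
    """Quadratic Bezier midline (base at origin, growing along +y) in cm.

    ``bend_frac`` offsets the control point sideways by that fraction of the
    length, emulating stem bending; the sampled polyline is rescaled so its
    arc length equals ``length_cm`` exactly.
    """
    if length_cm <= 0:
        raise ValueError("length_cm must be positive")
    p0 = np.array([0.0, 0.0])
    p1 = np.array([bend_frac * length_cm, 0.5 * length_cm])
    p2 = np.array([0.25 * bend_frac * length_cm, 1.0 * length_cm])
    t = np.linspace(0.0, 1.0, n_vertices)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    arc = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1])).sum()
    return pts * (length_cm / arc)


def _azimuth_direction(azimuth_deg: float) -> np.ndarray:
    """Unit (x, y) direction of an azimuth (clockwise from image-up, y down)."""
    a = math.radians(azimuth_deg)
    return np.array([math.sin(a), -math.cos(a)])


def _nearest_light(config: SceneConfig, bearing_deg: float, rng: np.random.Generator) -> float:
    """Lighting azimuth nearest to a bearing; ties broken at random."""
    diffs = [
        (abs((bearing_deg - az + 180.0) % 360.0 - 180.0), az)
        for az in config.lighting_azimuths_deg
    ]
    best = min(d for d, _ in diffs)
    cands = [az for d, az in diffs if abs(d - best) < 1e-9]
    return float(cands[0] if len(cands) == 1 else rng.choice(cands))


def sample_seedlings(
    config: SceneConfig,
    seed: int | None = None,
    age_h: float | None = None,
    length_range_cm: tuple[float, float] = (3.6, 4.4),
    tilt_range_deg: tuple[float, float] = (55.0, 75.0),
    width_px: float = 3.0,
) -> list[SeedlingGroundTruth]:
    """Draw one seedling per grid cell with phototropic lean.

    Each seedling leans toward the nearest corner grow lamp, with azimuth
    jitter inside the +-15 deg lighting band the rig's light angles span;
    cells equidistant from two lamps pick one at random. Lengths are drawn
    uniformly from ``length_range_cm`` (scaled by ``age_h / horizon_h``
    when an age is given) and tilts uniformly from ``tilt_range_deg``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if age_h is None:
        age_h = config.horizon_h
    age_scale = age_h / config.horizon_h
    seedlings = []
    half = (config.grid - 1) / 2.0
    for row in range(config.grid):
        for col in range(config.grid):
            dx, dy = col - half, row - half
            if dx == 0 and dy == 0:
                bearing = float(rng.choice(config.lighting_azimuths_deg))
            else:
                bearing = math.degrees(math.atan2(dx, -dy)) % 360.0
            prior = _nearest_light(config, bearing, rng)
            azimuth = prior + rng.uniform(
                -config.azimuth_tolerance_deg * 0.8, config.azimuth_tolerance_deg * 0.8
            )
            length = rng.uniform(*length_range_cm) * age_scale
            poly = bezier_midline(length, bend_frac=rng.uniform(-0.10, 0.10))
            seedlings.append(
                SeedlingGroundTruth(
                    id=row * config.grid + col + 1,
                    cell=(row, col),
                    polyline_cm=poly,
                    true_length_cm=length,
                    width_px=width_px,
                    azimuth_deg=azimuth % 360.0,
                    tilt_deg=float(rng.uniform(*tilt_range_deg)),
                    confidence=float(rng.uniform(0.45, 1.0)),
                    age_h=age_h,
                )
            )
    return seedlings


def _apparent_polyline_px(
    seedling: SeedlingGroundTruth,
    config: SceneConfig,
    anchor_px: np.ndarray,
    warp: bool = True,
) -> np.ndarray:
    """Project the midline to the image plane, centred on ``anchor_px``.

    Projection: uniform foreshortening by sin(tilt), rotation so the local
    "along" axis points at the lean azimuth, then conversion to pixels and
    the pincushion warp.
    """
    poly = seedling.polyline_cm * math.sin(math.radians(seedling.tilt_deg))
    d_along = _azimuth_direction(seedling.azimuth_deg)
    d_perp = np.array([-d_along[1], d_along[0]])
    pts = poly[:, 0:1] * d_perp + poly[:, 1:2] * d_along
    pts_px = pts * config.px_per_cm
    pts_px = pts_px - pts_px.mean(axis=0) + anchor_px
    if warp and config.k1 > 0:
        pts_px = apply_pincushion(pts_px, config.k1, config.center_px, config.half_diag_px)
    return pts_px


def stroke_probability_window(
    poly_px: np.ndarray, width_px: float, frame_px: int
) -> tuple[int, int, np.ndarray]:
    """Render a flat-capped stroke as a soft (anti-aliased) probability patch.

    Emulates a segmenter's floating-point output: pixel value is a linear
    ramp of the signed distance to the stroke boundary, 1 well inside,
    0.5 exactly on the ``width_px / 2`` outline, 0 outside. Distance is
    measured to segment interiors only (perpendicular projection inside the
    segment), so the stroke's extent equals the polyline extent (flat caps).

    Returns ``(y0, x0, values)`` where ``values`` is the float window and
    ``(x0, y0)`` its top-left pixel in frame coordinates.
    """
    half_w = width_px / 2.0
    pad = half_w + 2.0
    lo = np.floor(poly_px.min(axis=0) - pad).astype(int)
    hi = np.ceil(poly_px.max(axis=0) + pad).astype(int)
    x0, y0 = np.clip(lo, 0, frame_px - 1)
    x1, y1 = np.clip(hi, 0, frame_px - 1)
    xs = np.arange(x0, x1 + 1, dtype=float)
    ys = np.arange(y0, y1 + 1, dtype=float)
    gx = xs[None, :]
    gy = ys[:, None]
    dist2 = np.full((ys.size, xs.size), np.inf)
    for (ax, ay), (bx, by) in zip(poly_px[:-1], poly_px[1:]):
        abx, aby = bx - ax, by - ay
        L2 = abx * abx + aby * aby
        if L2 < 1e-12:
            continue
        t = ((gx - ax) * abx + (gy - ay) * aby) / L2
        px = ax + t * abx
        py = ay + t * aby
        d2 = (gx - px) ** 2 + (gy - py) ** 2
        np.minimum(dist2, np.where((t >= 0.0) & (t <= 1.0), d2, np.inf), out=dist2)
    values = np.clip(0.5 + (half_w - np.sqrt(dist2)), 0.0, 1.0)
    return int(y0), int(x0), values


def rasterize_stroke(poly_px: np.ndarray, width_px: float, frame_px: int):
    """Binary rasterization of a stroke: pixels whose value exceeds 0.5.

    Returns ``(rows, cols)`` index arrays in frame coordinates.
    """
    y0, x0, values = stroke_probability_window(poly_px, width_px, frame_px)
    rows, cols = np.nonzero(values > 0.5)
    return rows + y0, cols + x0


def generate_scene(
    config: SceneConfig,
    seedlings: list[SeedlingGroundTruth] | None = None,
    seed: int | None = None,
    age_h: float | None = None,
    return_masks: bool = False,
):
    """Render a label image and its exact ground-truth table.

    The label image is uint16 with 0 background and instance ids elsewhere.
    Overlapping instances are a generation error (real seedlings are soil-
    anchored in separate cells), so any pixel collision raises.

    With ``return_masks=True`` a third element is returned: a dict mapping
    instance id to ``(x0, y0, values)`` soft probability patches, the
    per-instance floating-point masks a segmenter would emit.
    """
    if seedlings is None:
        seedlings = sample_seedlings(config, seed=seed, age_h=age_h)
    label = np.zeros((config.frame_px, config.frame_px), dtype=np.uint16)
    soft_masks: dict[int, tuple[int, int, np.ndarray]] = {}
    records = []
    for s in seedlings:
        row, col = s.cell
        if not (0 <= row < config.grid and 0 <= col < config.grid):
            raise ValueError(f"seedling {s.id} cell {s.cell} outside the grid")
        anchor = np.array(
            [
                config.margin_px + (col + 0.5) * config.cell_px,
                config.margin_px + (row + 0.5) * config.cell_px,
            ]
        )
        poly_px = _apparent_polyline_px(s, config, anchor)
        y0, x0, values = stroke_probability_window(poly_px, s.width_px, config.frame_px)
        rr, cc = np.nonzero(values > 0.5)
        rr, cc = rr + y0, cc + x0
        if np.any(label[rr, cc] != 0):
            clash = int(label[rr, cc][label[rr, cc] != 0][0])
            raise ValueError(f"instance {s.id} overlaps instance {clash}")
        label[rr, cc] = s.id
        if return_masks:
            soft_masks[s.id] = (x0, y0, values)
        records.append(
            {
                "id": s.id,
                "row": row,
                "col": col,
                "true_length_cm": s.true_length_cm,
                "azimuth_deg": s.azimuth_deg,
                "tilt_deg": s.tilt_deg,
                "confidence": s.confidence,
                "age_h": s.age_h,
                "width_px": s.width_px,
                "centroid_x_px": float(cc.mean()) if cc.size else np.nan,
                "centroid_y_px": float(rr.mean()) if rr.size else np.nan,
            }
        )
    truth = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS)
    if return_masks:
        return label, truth, soft_masks
    return label, truth


def _measure_stroke_perimeter(poly_px: np.ndarray, width_px: float, frame_px: int):
    """Render a stroke alone and measure its 0.5 iso-contour perimeter."""
    y0, x0, values = stroke_probability_window(poly_px, width_px, frame_px)
    if not (values > 0.5).any():
        raise ValueError("stroke rasterized to zero pixels")
    contour = extract_contour(values)
    perim = perimeter(contour)
    cx, cy = mask_centroid(values)
    return perim, (cx + x0, cy + y0)


def _scene_cell_radii_px(config: SceneConfig) -> np.ndarray:
    """Radial distances of all grid-cell centres from the frame centre."""
    half = (config.grid - 1) / 2.0
    radii = []
    for row in range(config.grid):
        for col in range(config.grid):
            radii.append(config.cell_px * math.hypot(col - half, row - half))
    return np.asarray(radii)


def generate_calibration_set(
    config: SceneConfig,
    n_groups: int = 20,
    images_per_group: int = 7,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emulate the repeated calibration captures of the box.

    The calibration column is the box's main diagonal of ``images_per_group``
    seedlings. In every group the box is re-posed ``images_per_group`` times
    along a diagonal lighting axis so each calibration seedling in turn sits
    at the frame centre (the calibration point); the remaining seedlings land
    at radial distances drawn from the multiset of grid-cell radii of a
    measurement scene, so the calibration samples radius with the same
    density at which scenes are later measured.

    Returns one record per (group, image, seedling):
    ``group, image, seedling_id, radial_px, observed_perimeter_px,
    true_perimeter_px``.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if images_per_group < 1:
        raise ValueError("images_per_group must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_seed = images_per_group
    lengths = np.linspace(3.6, 4.4, n_seed)
    tilts = rng.uniform(55.0, 75.0, size=n_seed)
    bends = rng.uniform(-0.08, 0.08, size=n_seed)
    center = np.asarray(config.center_px)
    scene_radii = _scene_cell_radii_px(config)
    nonzero_radii = scene_radii[scene_radii > 0]
    # keep warped stroke tips inside the frame
    max_radius = 0.995 * scene_radii.max()

    records = []
    for g in range(n_groups):
        axis = float(rng.choice([45.0, 135.0])) + rng.uniform(-3.0, 3.0)
        axis_dir = _azimuth_direction(axis)
        perp_dir = np.array([-axis_dir[1], axis_dir[0]])
        for i in range(images_per_group):
            for j in range(n_seed):
                if j == i:
                    radius = rng.uniform(0.0, 40.0)
                else:
                    radius = float(rng.choice(nonzero_radii)) + rng.uniform(-15.0, 15.0)
                radius = min(radius, max_radius)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                s = SeedlingGroundTruth(
                    id=j + 1,
                    cell=(0, j),
                    polyline_cm=bezier_midline(float(lengths[j]), float(bends[j])),
                    true_length_cm=float(lengths[j]),
                    width_px=3.0,
                    azimuth_deg=(axis + rng.uniform(-8.0, 8.0)) % 360.0,
                    tilt_deg=float(tilts[j]),
                    confidence=1.0,
                    age_h=config.horizon_h,
                )
                perp_off = rng.uniform(-10, 10)
                # pull the pose inward until the warped stroke clears the
                # frame border: a cropped mask would corrupt the perimeter
                for _ in range(6):
                    anchor = center + sign * radius * axis_dir + perp_off * perp_dir
                    poly = _apparent_polyline_px(s, config, anchor, warp=True)
                    margin = 2.0 + s.width_px
                    overshoot = max(
                        margin - poly.min(),
                        poly.max() - (config.frame_px - 1 - margin),
                        0.0,
                    )
                    if overshoot == 0.0:
                        break
                    radius = max(radius - 1.2 * overshoot, 0.0)
                obs_perim, obs_centroid = _measure_stroke_perimeter(
                    poly, s.width_px, config.frame_px
                )
                poly_true = _apparent_polyline_px(s, config, center, warp=False)
                true_perim, _ = _measure_stroke_perimeter(
                    poly_true, s.width_px, config.frame_px
                )
                records.append(
                    {
                        "group": g,
                        "image": i,
                        "seedling_id": j + 1,
                        "radial_px": float(
                            np.hypot(obs_centroid[0] - center[0], obs_centroid[1] - center[1])
                        ),
                        "observed_perimeter_px": obs_perim,
                        "true_perimeter_px": true_perim,
                        "true_length_cm": float(lengths[j]),
                    }
                )
    obs = pd.DataFrame.from_records(records)
    n_images = len(obs[["group", "image"]].drop_duplicates())
    if n_images != n_groups * images_per_group:
        raise RuntimeError(
            f"emitted {n_images} images, expected {n_groups * images_per_group}"
        )
    return obs


def generate_growth_series(
    design: TreatmentDesign,
    config: SceneConfig,
    seed: int | None = None,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Simulate per-group length-versus-time series.

    Lengths follow ``L(t) = rate * t + noise`` with the rate from the
    treatment design, Gaussian measurement noise of ``design.noise_sd_cm``
    and clipping at zero; the time grid is 0, dt, ... up to the horizon.

    Returns columns ``salt_mmolL, fe_mgL, replicate, t_min, length_cm``.
    """
    if config.n_frames < 2:
        raise ValueError("horizon and interval must yield at least 2 time points")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t_min = config.time_grid_min()
    t_h = t_min / 60.0
    frames = []
    for salt in design.salt_levels_mmolL:
        for fe in design.fe_levels_mgL:
            rate = design.rate_cm_per_h(salt, fe)
            if rate < 0:
                raise ValueError(f"negative growth rate for (salt={salt}, fe={fe})")
            for rep in range(n_replicates):
                noise = rng.normal(0.0, design.noise_sd_cm, size=t_h.size)
                if design.noise_sd_cm == 0:
                    noise = np.zeros_like(t_h)
                lengths = np.clip(rate * t_h + noise, 0.0, None)
                frames.append(
                    pd.DataFrame(
                        {
                            "salt_mmolL": salt,
                            "fe_mgL": fe,
                            "replicate": rep,
                            "t_min": t_min,
                            "length_cm": lengths,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)
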