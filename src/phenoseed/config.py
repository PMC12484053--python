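"""Configuration objects for the virtual imaging rig and the treatment design.

The rig emulates a fixed top-down RGB camera over a square germination box:
a ``frame_px`` x ``frame_px`` sensor viewing a ``box_cm`` x ``box_cm`` box that
fills the frame, seedlings arranged on a ``grid`` x ``grid`` lattice, a single
radial (pincushion) distortion coefficient ``k1``, grow lights at the four
diagonal compass azimuths, and a capture clock ticking every
``capture_interval_min`` minutes over a ``horizon_h``-hour run.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = ["SceneConfig", "TreatmentDesign", "load_config", "dump_config"]


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics and timing constants of the virtual imaging rig.

    Parameters
    ----------
    frame_px:
        Sensor side length in pixels. The box is assumed to fill the frame,
        so the physical scale is ``box_cm / frame_px`` cm per pixel.
    box_cm:
        Physical side length of the germination box in cm.
    grid:
        Seedlings per row and per column (``grid**2`` seedlings in total).
    k1:
        Pincushion coefficient of the single-term radial distortion model
        ``r_d = r * (1 + k1 * r**2)`` with ``r`` normalised by the half frame
        diagonal. ``k1 = 0`` is a distortion-free camera.
    lighting_azimuths_deg:
        Azimuths (clockwise from image-up) of the grow lights. Seedlings lean
        toward these directions; angle smoothing shrinks detector azimuths
        toward the nearest one.
    azimuth_tolerance_deg:
        Half-width of the band around each lighting azimuth within which a
        raw angle is accepted unshrunk.
    capture_interval_min:
        Minutes between consecutive captures.
    horizon_h:
        Total observed growth span in hours.
    sowing_margin_cm:
        Border between the box wall and the outermost seed row. Seeds are
        sown on a grid inset by this margin, as in a real germination box.
    seed:
        Default RNG seed used when no explicit seed is passed to a generator.
    """

    frame_px: int = 1600
    box_cm: float = 25.0
    grid: int = 7
    k1: float = 0.08
    sowing_margin_cm: float = 1.25
    lighting_azimuths_deg: tuple[float, ...] = (45.0, 135.0, 225.0, 315.0)
    azimuth_tolerance_deg: float = 15.0
    capture_interval_min: float = 50.0
    horizon_h: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_px <= 0:
            raise ValueError("frame_px must be positive")
        if self.box_cm <= 0:
            raise ValueError("box_cm must be positive")
        if self.grid < 1:
            raise ValueError("grid must be >= 1")
        if self.k1 < 0:
            raise ValueError("k1 must be non-negative")
        if not 0 <= self.sowing_margin_cm < self.box_cm / 2:
            raise ValueError("sowing_margin_cm must lie in [0, box_cm / 2)")
        if not 0 < self.capture_interval_min <= self.horizon_h * 60.0:
            raise ValueError("capture_interval_min must lie in (0, horizon_h*60]")

    @property
    def center_px(self) -> tuple[float, float]:
        """Optical centre (x, y) of the frame in pixels."""
        return (self.frame_px / 2.0, self.frame_px / 2.0)

    @property
    def half_diag_px(self) -> float:
        """Half frame diagonal in pixels; the radial normalisation length."""
        return self.frame_px * math.sqrt(2.0) / 2.0

    @property
    def px_per_cm(self) -> float:
        return self.frame_px / self.box_cm

    @property
    def margin_px(self) -> float:
        """Sowing margin in pixels."""
        return self.sowing_margin_cm * self.px_per_cm

    @property
    def cell_px(self) -> float:
        """Sowing-grid cell pitch in pixels (inside the margin)."""
        return (self.frame_px - 2.0 * self.margin_px) / self.grid

    @property
    def n_frames(self) -> int:
        """Number of captures on the time grid 0, dt, ..., <= horizon."""
        return int(self.horizon_h * 60.0 // self.capture_interval_min) + 1

    def time_grid_min(self):
        import numpy as np

        return np.arange(self.n_frames, dtype=float) * self.capture_interval_min


def _default_salt_multiplier() -> dict[float, float]:
    # Monotone inhibition with NaCl concentration; growth at 150 mmol/L is
    # residual and is zeroed for the unprimed control via the fe table.
    return {0.0: 1.0, 30.0: 0.85, 60.0: 0.70, 90.0: 0.55, 120.0: 0.40, 150.0: 0.22}


def _default_fe_multiplier() -> dict[tuple[float, float], float]:
    """Nano-iron effect relative to the unprimed control, per salt level.

    The table encodes the qualitative dose-response structure of the study
    system: 300 mg/L promotes growth under every salt level (strongest on
    average), 20 mg/L is second-best overall but inhibits at 120 mmol/L,
    50 mg/L dips slightly at 90 mmol/L, 100 mg/L inhibits at 120 mmol/L,
    200 mg/L inhibits at 60 and 90 mmol/L, and the unprimed control does not
    grow at all at 150 mmol/L.
    """
    table = {
        0.0: {0.0: 1.00, 30.0: 1.00, 60.0: 1.00, 90.0: 1.00, 120.0: 1.00, 150.0: 0.0},
        20.0: {0.0: 1.30, 30.0: 1.45, 60.0: 1.25, 90.0: 1.35, 120.0: 0.90, 150.0: 1.50},
        50.0: {0.0: 1.20, 30.0: 1.15, 60.0: 1.20, 90.0: 0.95, 120.0: 1.15, 150.0: 1.40},
        100.0: {0.0: 1.10, 30.0: 1.15, 60.0: 1.10, 90.0: 1.05, 120.0: 0.85, 150.0: 1.30},
        200.0: {0.0: 1.05, 30.0: 1.10, 60.0: 0.90, 90.0: 0.90, 120.0: 1.05, 150.0: 1.20},
        300.0: {0.0: 1.50, 30.0: 1.10, 60.0: 1.40, 90.0: 1.45, 120.0: 1.35, 150.0: 1.90},
    }
    return {(fe, salt): v for fe, row in table.items() for salt, v in row.items()}


@dataclass(frozen=True)
class TreatmentDesign:
    """Factorial salt x nano-iron design and the linear growth model.

    The noise-free elongation rate of group (salt, fe) is
    ``base_rate_cm_per_h * salt_multiplier[salt] * fe_multiplier[(fe, salt)]``.
    """

    salt_levels_mmolL: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    fe_levels_mgL: tuple[float, ...] = (0.0, 20.0, 50.0, 100.0, 200.0, 300.0)
    base_rate_cm_per_h: float = 0.05
    salt_multiplier: Mapping[float, float] = field(default_factory=_default_salt_multiplier)
    fe_multiplier: Mapping[tuple[float, float], float] = field(
        default_factory=_default_fe_multiplier
    )
    noise_sd_cm: float = 0.05

    def __post_init__(self) -> None:
        if self.base_rate_cm_per_h < 0:
            raise ValueError("base_rate_cm_per_h must be non-negative")
        if self.noise_sd_cm < 0:
            raise ValueError("noise_sd_cm must be non-negative")
        for salt in self.salt_levels_mmolL:
            if salt not in self.salt_multiplier:
                raise ValueError(f"salt_multiplier missing level {salt}")
            if not 0 <= self.salt_multiplier[salt] <= 1:
                raise ValueError("salt_multiplier values must lie in [0, 1]")
            for fe in self.fe_levels_mgL:
                if (fe, salt) not in self.fe_multiplier:
                    raise ValueError(f"fe_multiplier missing cell (fe={fe}, salt={salt})")
                if self.fe_multiplier[(fe, salt)] < 0:
                    raise ValueError("fe_multiplier values must be non-negative")
        if self.rate_cm_per_h(150.0, 0.0) != 0.0:
            raise ValueError("unprimed control must not grow at 150 mmol/L")
        means = {
            fe: sum(self.fe_multiplier[(fe, s)] for s in self.salt_levels_mmolL)
            for fe in self.fe_levels_mgL
        }
        if max(means, key=means.get) != max(self.fe_levels_mgL):
            raise ValueError("highest fe level must have the largest averaged effect")

    def rate_cm_per_h(self, salt: float, fe: float) -> float:
        """Noise-free elongation rate of treatment cell (salt, fe)."""
        return (
            self.base_rate_cm_per_h
            * self.salt_multiplier[salt]
            * self.fe_multiplier[(fe, salt)]
        )


def _as_plain(obj):
    if dataclasses.is_dataclass(obj):
        out = {}
        for f in dataclasses.fields(obj):
            out[f.name] = _as_plain(getattr(obj, f.name))
        return out
    if isinstance(obj, Mapping):
        # YAML cannot key on tuples; serialise as "fe|salt" strings.
        return {
            ("|".join(str(x) for x in k) if isinstance(k, tuple) else k): v
            for k, v in obj.items()
        }
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def dump_config(scene: SceneConfig, design: TreatmentDesign, path) -> None:
    """Write both config sections to a YAML file."""
    payload = {"scene": _as_plain(scene), "design": _as_plain(design)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_config(path) -> tuple[SceneConfig, TreatmentDesign]:
    """Read a YAML file written by :func:`dump_config` (or hand-edited)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    scene_raw = payload.get("scene", {})
    if "lighting_azimuths_deg" in scene_raw:
        scene_raw["lighting_azimuths_deg"] = tuple(scene_raw["lighting_azimuths_deg"])
    scene = SceneConfig(**scene_raw)
    design_raw = payload.get("design", {})
    for key in ("salt_levels_mmolL", "fe_levels_mgL"):
        if key in design_raw:
            design_raw[key] = tuple(float(x) for x in design_raw[key])
    if "salt_multiplier" in design_raw:
        design_raw["salt_multiplier"] = {
            float(k): float(v) for k, v in design_raw["salt_multiplier"].items()
        }
    if "fe_multiplier" in design_raw:
        design_raw["fe_multiplier"] = {
            tuple(float(x) for x in k.split("|")): float(v)
            for k, v in design_raw["fe_multiplier"].items()
        }
    design = TreatmentDesign(**design_raw)
    return scene, design
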