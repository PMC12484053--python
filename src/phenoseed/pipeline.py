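"""End-to-end reproducible run: simulate, calibrate, measure, score.

One call renders a synthetic scene, generates and fits the distortion
calibration, measures every retained instance, simulates the treatment
growth series, scores vitality, and writes everything plus a manifest
(config hash, seed, versions, per-stage record counts and warnings) to an
output directory. Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .config import SceneConfig, TreatmentDesign, dump_config
from .scene import generate_calibration_set, generate_growth_series, generate_scene
from .truelength import age_filter, fit_ring_calibration, measure_scene, smooth_angle
from .vitality import vitality_report

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    design: TreatmentDesign = field(default_factory=TreatmentDesign)
    n_rings: int = 3
    n_calibration_groups: int = 20
    images_per_group: int = 7
    smoothing_lambda: float = 0.5
    tilt_clamp: tuple[float, float] = (30.0, 60.0)
    age_cutoff_h: float = 60.0
    strategy: str = "per-salt"
    seed: int = 0


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def _config_hash(cfg: RunConfig) -> str:
    def plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {str(k): plain(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        if isinstance(obj, (tuple, list)):
            return [plain(x) for x in obj]
        return obj

    blob = json.dumps(plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages into ``out_dir`` and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "phenoseed_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_sha256": _config_hash(config),
        "strategy": config.strategy,
        "stages": {},
        "warnings": [],
    }
    caught: list[str] = []

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # 1. scene
        scene_cfg = config.scene
        try:
            label, truth = generate_scene(scene_cfg, seed=seeds[0])
        except ValueError as err:
            raise RuntimeError(f"stage 'simulate' failed: {err}") from err
        iio.imwrite(out / "scene_labels.png", label.astype(np.uint16))
        truth.to_csv(out / "scene_truth.csv", index=False)
        record("simulate", instances=len(truth))

        # 2-3. calibration
        try:
            calib_obs = generate_calibration_set(
                scene_cfg,
                n_groups=config.n_calibration_groups,
                images_per_group=config.images_per_group,
                seed=seeds[1],
            )
            model = fit_ring_calibration(
                calib_obs, n_rings=config.n_rings, center_px=scene_cfg.center_px
            )
        except ValueError as err:
            raise RuntimeError(f"stage 'calibrate' failed: {err}") from err
        calib_obs.to_csv(out / "calibration_observations.csv", index=False)
        model.to_frame().to_csv(out / "calibration_model.csv", index=False)
        record(
            "calibrate",
            observations=len(calib_obs),
            images=config.n_calibration_groups * config.images_per_group,
            rings=model.n_rings,
        )

        # 4. measurement with angle smoothing and age filtering
        try:
            retained = age_filter(truth, cutoff_age_h=config.age_cutoff_h)
            angles = retained[["id", "azimuth_deg", "tilt_deg"]].copy()
            angles["smoothed_azimuth_deg"] = [
                smooth_angle(
                    a,
                    scene_cfg.lighting_azimuths_deg,
                    config.smoothing_lambda,
                    scene_cfg.azimuth_tolerance_deg,
                )
                for a in angles["azimuth_deg"]
            ]
            kept_label = np.where(
                np.isin(label, retained["id"].to_numpy()), label, 0
            ).astype(np.uint16)
            lengths = measure_scene(
                kept_label, angles, model, scene_cfg, clamp=config.tilt_clamp
            )
        except ValueError as err:
            raise RuntimeError(f"stage 'measure' failed: {err}") from err
        lengths = lengths.merge(
            truth[["id", "true_length_cm"]], on="id", how="left"
        )
        angles.to_csv(out / "angles.csv", index=False)
        lengths.to_csv(out / "lengths.csv", index=False)
        record(
            "measure",
            detected=len(truth),
            retained=len(retained),
            measured=len(lengths),
        )
        if len(lengths) != len(retained):
            raise RuntimeError(
                "stage 'measure' failed: length rows != retained instances"
            )

        # 5. growth series
        try:
            series = generate_growth_series(config.design, scene_cfg, seed=seeds[2])
        except ValueError as err:
            raise RuntimeError(f"stage 'growth' failed: {err}") from err
        series.to_csv(out / "growth_series.csv", index=False)
        record(
            "growth",
            groups=len(series[["salt_mmolL", "fe_mgL"]].drop_duplicates()),
            rows=len(series),
        )

        # 6. vitality
        try:
            cell_scores, fe_scores = vitality_report(
                series, config.design, strategy=config.strategy
            )
        except ValueError as err:
            raise RuntimeError(f"stage 'vitality' failed: {err}") from err
        cell_scores.to_csv(out / "vitality_cells.csv", index=False)
        fe_scores.to_csv(out / "vitality_by_fe.csv", index=False)
        record("vitality", cells=len(cell_scores), fe_levels=len(fe_scores))

        caught = [str(w.message) for w in wlist]

    manifest["warnings"] = caught
    dump_config(config.scene, config.design, out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
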