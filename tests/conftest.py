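"""Shared fixtures: one seeded distorted scene + calibration set per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import phenoseed as ps

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


SCENE_SEED = 11
CALIB_SEED = 12


@pytest.fixture(scope="session")
def scene_cfg() -> ps.SceneConfig:
    return ps.SceneConfig(seed=1)


@pytest.fixture(scope="session")
def fixture_scene(scene_cfg):
    """Seeded distorted scene: label image, ground truth, soft masks."""
    label, truth, masks = ps.generate_scene(
        scene_cfg, seed=SCENE_SEED, return_masks=True
    )
    return label, truth, masks


@pytest.fixture(scope="session")
def calibration_obs(scene_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ps.generate_calibration_set(scene_cfg, seed=CALIB_SEED)


@pytest.fixture(scope="session")
def calibration_model(scene_cfg, calibration_obs):
    return ps.fit_ring_calibration(
        calibration_obs, n_rings=3, center_px=scene_cfg.center_px
    )


@pytest.fixture(scope="session")
def scene_measurements(scene_cfg, fixture_scene, calibration_model):
    """Corrected and uncorrected length tables joined with ground truth."""
    label, truth, masks = fixture_scene
    angles = truth[["id", "tilt_deg"]]
    out = {}
    for key, apply_corr in (("corrected", True), ("uncorrected", False)):
        df = ps.measure_scene(
            masks, angles, calibration_model, scene_cfg, apply_correction=apply_corr
        )
        df = df.merge(truth[["id", "true_length_cm"]], on="id")
        df["rel_err"] = (df["length_cm"] - df["true_length_cm"]) / df["true_length_cm"]
        out[key] = df
    return out


def random_blob(rng: np.random.Generator, size: int = 48) -> np.ndarray:
    """A random smooth binary blob kept clear of the image border."""
    from skimage.filters import gaussian

    field = gaussian(rng.normal(size=(size, size)), sigma=4)
    mask = field > np.quantile(field, 0.85)
    border = max(size // 8, 2)
    mask[:border] = mask[-border:] = False
    mask[:, :border] = mask[:, -border:] = False
    if not mask.any():
        mask[size // 2, size // 2] = True
    return mask
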