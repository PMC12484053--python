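"""Render the virtual rig: one 90 h scene, the calibration captures and the
treatment growth series.

Writes results/scene_labels.png, results/scene_truth.csv,
results/calibration_observations.csv and results/growth_series.csv.
"""

from pathlib import Path

import imageio.v3 as iio
import numpy as np

import phenoseed as ps

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = ps.SceneConfig(seed=SEED)
    design = ps.TreatmentDesign()

    label, truth = ps.generate_scene(cfg, seed=SEED)
    iio.imwrite(RESULTS / "scene_labels.png", label.astype(np.uint16))
    truth.to_csv(RESULTS / "scene_truth.csv", index=False)
    print(
        f"scene: {len(truth)} seedlings on a {cfg.grid}x{cfg.grid} grid, "
        f"lengths {truth.true_length_cm.min():.2f}-{truth.true_length_cm.max():.2f} cm, "
        f"tilts {truth.tilt_deg.min():.0f}-{truth.tilt_deg.max():.0f} deg"
    )

    obs = ps.generate_calibration_set(cfg, seed=SEED + 1)
    obs.to_csv(RESULTS / "calibration_observations.csv", index=False)
    n_img = len(obs[["group", "image"]].drop_duplicates())
    print(f"calibration: {n_img} captures, {len(obs)} perimeter observations")

    series = ps.generate_growth_series(design, cfg, seed=SEED + 2)
    series.to_csv(RESULTS / "growth_series.csv", index=False)
    n_groups = len(series[["salt_mmolL", "fe_mgL"]].drop_duplicates())
    print(f"growth: {n_groups} treatment groups x {series.groupby(['salt_mmolL','fe_mgL']).size().iloc[0]} time points")


if __name__ == "__main__":
    main()
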