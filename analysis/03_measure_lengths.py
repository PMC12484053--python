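"""Measure physical seedling lengths on the simulated scene.

Re-renders the seeded scene (deterministic), applies the fitted ring
calibration and tilt correction, and compares against exact ground truth.
Writes results/lengths.csv and prints error statistics plus the
module-versus-truth agreement slope.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import phenoseed as ps

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = ps.SceneConfig(seed=SEED)
    _, truth, masks = ps.generate_scene(cfg, seed=SEED, return_masks=True)
    model_df = pd.read_csv(RESULTS / "calibration_model.csv")
    model = ps.CalibrationModel(
        center_px=cfg.center_px,
        ring_edges_px=model_df.outer_edge_px.to_numpy(),
        ring_ratio=model_df.ratio.to_numpy(),
        n_obs=model_df.n_obs.to_numpy(),
    )

    retained = ps.age_filter(truth, cutoff_age_h=60.0)
    angles = retained[["id", "tilt_deg"]]
    kept = {i: masks[i] for i in retained.id}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr = ps.measure_scene(kept, angles, model, cfg)
        unc = ps.measure_scene(kept, angles, model, cfg, apply_correction=False)

    corr = corr.merge(truth[["id", "true_length_cm"]], on="id")
    corr.to_csv(RESULTS / "lengths.csv", index=False)
    rel = lambda df: np.abs(df.length_cm - df.true_length_cm) / df.true_length_cm
    slope, intercept = ps.agreement_slope(corr.true_length_cm, corr.length_cm)
    print(f"retained {len(retained)}/{len(truth)} instances after the age filter")
    print(
        f"median |relative error|: corrected {100*np.median(rel(corr)):.2f}%  "
        f"uncorrected {100*np.median(rel(unc.merge(truth[['id','true_length_cm']], on='id'))):.2f}%"
    )
    print(f"agreement with ground truth: slope {slope:.5f}, intercept {intercept:.4f} cm")


if __name__ == "__main__":
    main()
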