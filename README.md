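# phenoseed

Ground-truth seedling length from top-down instance masks, and dual-index
growth-vitality scoring for stress-treatment experiments.

High-throughput germination rigs photograph a seedling box from above and
segment each seedling into a pixel mask. Two optical effects then stand
between the mask and the biology: **radial pincushion distortion** spreads
edge pixels outward, so seedlings far from the image centre are measured too
long, and **phototropic lean** tilts seedlings out of the image plane toward
the grow lamps, so their top-down projection is too short. `phenoseed`
implements the full chain that turns raw masks into physical lengths and
treatment-level vitality scores, plus a synthetic-scene generator with exact
ground truth that stands in for the camera and neural segmenter, so every
step of the chain can be validated quantitatively.

## The measurement model

For a seedling mask with closed-contour pixel perimeter $P$ (traced at the
0.5 iso-level, marching-squares style), centroid at radial distance $r$
from the calibration point, and lean tilt $\theta$ from the vertical axis:

$$L \;=\; \frac{P \cdot \rho(r)}{2}\;\cdot\;\frac{1}{\sin\big(\max(\theta,\,30^\circ)\big)}\;\cdot\;\frac{\text{box}_{cm}}{\text{frame}_{px}}$$

* $P/2$ — a thin seedling's outline runs up one side and down the other, so
  half the closed perimeter approximates the midline length;
* $\rho(r)$ — an empirical per-ring correction factor: seedlings are
  stratified into concentric rings and each ring's factor is the median
  ratio of centre-to-ring perimeters of the *same physical seedlings*,
  estimated from repeated captures of the box at different poses (20 groups,
  140 images by default). No distortion coefficient is ever assumed;
* $1/\sin\theta$ — inverts the top-down foreshortening of the lean, with the
  tilt clamped below $30^\circ$ so near-vertical seedlings are not amplified
  without bound;
* the final factor is the pixel scale of the box (25 cm across 1600 px).

Treatment effects are scored with a **static vitality** (mean seedling
length) and a **dynamic vitality** (slope of the length-versus-time OLS
fit). Both are divided by their maximum under equivalent conditions,
combined with equal 0.5 weights, averaged per nano-iron priming dose, and
expressed as percentage shares.

## Worked example

```python
import numpy as np
import phenoseed as ps

cfg = ps.SceneConfig(seed=1)                  # 1600 px / 25 cm box, 7x7 grid, k1=0.08
label, truth, masks = ps.generate_scene(cfg, seed=1, return_masks=True)
obs   = ps.generate_calibration_set(cfg, seed=2)        # 20 groups, 140 captures
model = ps.fit_ring_calibration(obs, n_rings=3, center_px=cfg.center_px)

lengths = ps.measure_scene(masks, truth[["id", "tilt_deg"]], model, cfg)
merged  = lengths.merge(truth[["id", "true_length_cm"]], on="id")
err = np.abs(merged.length_cm - merged.true_length_cm) / merged.true_length_cm
print(f"median |error| {100 * err.median():.2f}%")
print("slope", round(ps.agreement_slope(merged.true_length_cm, merged.length_cm)[0], 5))
```

prints (seeded run):

```
median |error| 1.18%
slope 1.04487
```

meaning the corrected module lengths track exact ground truth to about 1%
at the scene median, and regressing module output on truth gives a line of
slope ≈ 1 — the agreement check used to validate the measurement chain.
Without the ring correction the outer seedlings are over-measured by ~11%
(median); the fitted 3-ring model reduces that ~7-fold.

The same steps are available as numbered drivers:

```bash
python analysis/01_simulate_scene.py            # scene + captures + growth series
python analysis/02_fit_distortion_calibration.py
python analysis/03_measure_lengths.py
python analysis/04_score_vitality.py            # 300 mg/L ranks first (20.9% share)
python analysis/05_model_complexity.py
```

or as a CLI (`phenoseed simulate|calibrate|measure|vitality|complexity|run-all`).
Tables land in `results/`.

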