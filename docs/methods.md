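# Methods

## Problem setting

A fixed overhead RGB camera observes a 25 cm × 25 cm germination box that
fills a 1600 × 1600 px frame. Rice seedlings sit on a 7 × 7 grid and are
photographed every 50 minutes over 90 hours (109 frames). An instance
segmenter (not part of this package) outputs one floating-point probability
mask per seedling plus an orientation estimate. The package's job starts
there: convert each mask into a physical length, correct the two dominant
optical biases, and aggregate per-treatment series into vitality scores for
a 6 × 6 factorial of NaCl stress (0–150 mmol/L) by nano-iron-oxide seed
priming (0–300 mg/L).

## Measurement chain

1. **Perimeter.** The instance contour is traced at the 0.5 iso-level of the
   mask (marching squares) and its length is the Euclidean vertex walk. On
   floating-point masks the 0.5 crossing is interpolated sub-pixel, which
   matters for 3-px-wide seedlings: hard binarization before tracing adds an
   orientation-dependent staircase bias of up to +5% on oblique strokes,
   whereas the sub-pixel contour is orientation-neutral. Binary masks are
   accepted (the contour then runs midway between pixel centres) but soft
   masks are the preferred input.
2. **Half-perimeter rule.** A thin seedling's closed outline is twice its
   midline plus an $O(\text{width})$ end-cap term, so $P/2$ estimates the
   midline length with an absolute bias of roughly the stroke width
   (~3 px ≈ 1–2% for 150–270 px seedlings). The bias shrinks with seedling
   length and is visible in the agreement slope being ~1.01–1.04 rather
   than exactly 1.
3. **Ring-calibrated distortion correction.** The lens exhibits pincushion
   distortion: with $r$ the distance from the optical centre normalised by
   the half frame diagonal, a point at radius $r$ maps to $r(1 + k_1 r^2)$.
   A radially oriented object's arc length stretches by $\approx 1 + 3k_1
   r^2$ — +14% at the box corners for $k_1 = 0.08$. The corrector never
   assumes $k_1$: the same physical seedlings are re-captured at many poses
   (20 groups × 7 images), each capture yielding (seedling, radial
   distance, perimeter) triplets, and the per-ring factor is the median
   across seedlings of (mean perimeter at centre) / (mean perimeter in the
   ring). Applying the factor of the centroid's ring maps any observed
   perimeter to its centre-equivalent value.
4. **Ring stratification.** Default `anchored`: the innermost ring is a
   narrow disc (7% of the observed radial span) around the calibration
   point — its factor is pinned at 1, which is only valid where distortion
   is negligible — and the remaining annulus is split into rings of equal
   area (equal width in $r^2$). Because the warp grows with $r^2$,
   equal-area rings spread the within-ring warp variation evenly; a wide
   pinned inner ring, or an outer ring spanning half the warp range (both
   of which plain equal-width stratification produces), measurably degrades
   recovery. Plain equal-width rings remain available via
   `stratify="equal-width"`, and explicit edges override both.
5. **Tilt correction.** Phototropism tilts seedlings toward the grow lamps;
   a seedling at tilt $\theta$ from the vertical projects to
   $\sin\theta$ of its length in the top-down view. The correction
   multiplies by $1/\sin(\max(\theta, 30^\circ))$. The projection law is the
   pinhole approximation for a straight stem lying in the vertical plane of
   its lean azimuth. The lower clamp at 30° prevents unbounded
   amplification of near-vertical seedlings, for which the top-down view
   simply carries little length information; tilts above the trusted
   lighting band (upper clamp value 60°) need *less* correction, so they
   are used as-is — capping them would inflate in-plane seedlings by 15%.
6. **Angle smoothing (diagnostic).** Detector azimuths are shrunk toward the
   nearest lighting azimuth (45/135/225/315°) on the circle with weight
   λ, except within the ±15° band where the raw angle is physically
   plausible and passes unchanged. The smoothed azimuth drives the
   rotation-alignment diagnostic (`rotate_align`, an exact isometry); the
   length computation itself uses only the tilt.
7. **Age-dependent filtering.** Detections with confidence ≥ 0.4 are kept
   while seedlings are young (tillering, before the 60 h default cutoff;
   weak seedlings are biologically informative) and ≥ 0.6 afterwards
   (jointing; noise filtering). The cutoff hour is a config parameter since
   stage boundaries are biological, not clock, quantities.

## Vitality scoring

Per treatment cell: static vitality = mean length over the series; dynamic
vitality = OLS slope of length on time (cm/h). Negative slopes are floored
at zero before normalisation (a shrinking group has no dynamic vitality,
not negative vitality). "Under equivalent conditions" is read as per-salt
normalisation: within each salt level both indicators are divided by their
level maximum, combined with weights 0.5/0.5, then averaged per iron dose
across salt levels and expressed as a share of the dose sum. Because the
aggregation is genuinely ambiguous, a `global` strategy (one pooled maximum
per indicator) is provided behind the same interface; on the default
generator both rank the 300 mg/L dose first.

## Synthetic scene generator

The generator replaces the camera + segmenter with a controlled emulation
carrying exact ground truth.

* **Midlines** are quadratic Béziers (base, control, tip) rescaled so arc
  length equals the drawn true length exactly; stroke width 3 px.
* **Placement**: one seedling per grid cell, sown with a 1.25 cm border
  margin as in a real box. Default lengths at the 90 h endpoint are
  U(3.6, 4.4) cm (≈ 0.04–0.05 cm/h average elongation).
* **Lean**: toward the nearest corner grow lamp (the measured lighting
  azimuths), with jitter inside the ±15° band; tilts U(55, 75)° from the
  vertical at the late stage.
* **Rendering**: the midline is foreshortened by $\sin(\text{tilt})$,
  rotated to its azimuth, converted to pixels, warped by the pincushion
  model ($k_1 = 0.08$, normalised by the half frame diagonal) and rendered
  as a flat-capped stroke. Per-instance masks are soft: each pixel holds a
  linear ramp of its signed distance to the stroke outline (1 inside, 0.5
  on the outline, 0 outside), which is what a probability-mask segmenter
  produces and what the sub-pixel contour convention expects. The label
  image thresholds these at 0.5; overlapping instances raise an error.
* **Calibration captures** re-pose a diagonal column of 7 seedlings so that
  each seedling in turn sits at the frame centre while the others land at
  radial distances drawn from the multiset of scene grid-cell radii — the
  calibration samples radius with the same density at which scenes are
  later measured. Poses whose warped stroke would cross the frame border
  are pulled inward, because a cropped mask yields a corrupted perimeter.
* **Growth series**: $L(t) = \text{base rate} \times s(\text{salt}) \times
  f(\text{fe}, \text{salt}) \times t + \varepsilon$, clipped at zero, with
  $\varepsilon \sim N(0, 0.05^2)$ cm per 50-min sample. The dose–response
  table $f$ encodes the qualitative structure of the studied system: the
  unprimed control does not grow at 150 mmol/L; 300 mg/L promotes growth
  under every salt level and has the largest average effect; 20 mg/L is
  second-best overall but inhibits at 120 mmol/L; 200 mg/L inhibits at
  60–90 mmol/L. Replicate count per cell is a free parameter (default 1).

### What the generator does and does not emulate

It reproduces the geometry (scale, grid, distortion, lean) and the sampling
structure (capture counts, time grid, factorial design) exactly, so passing
tests demonstrate that the correction and scoring mathematics recover known
truth under the stated optical model. It does **not** emulate segmentation
failures (adhesion, splits, missed weak seedlings beyond the confidence
model), soil background, leaf branching, tangential lens distortion, or
non-linear growth phases. Accuracy numbers on synthetic scenes are
therefore upper bounds for real imagery, not forecasts.

## Numerical choices

* Perimeter = vertex walk of the traced contour; multi-component masks keep
  the largest component (smaller fragments are segmentation specks).
* AP for detection evaluation uses greedy confidence-ordered matching and
  all-point (integral) interpolation over thresholds 0.5:0.05:0.95.
* Ring ratios use medians across seedlings (robust to a bad mask); ring
  assignment of a centroid beyond the outermost edge falls back to the
  outermost ratio with a warning.
* OLS fits use `numpy.polyfit`; degenerate inputs (constant time, constant
  manual lengths, empty series) raise rather than return NaN.
* All generators take explicit integer seeds; identical config + seed is
  byte-identical end to end (the pipeline manifest records the config hash
  and per-stage seeds).

## Analysis sizes

The bundled analysis and acceptance runs use one 49-seedling scene, a
20-group/140-capture calibration set, and 500 replicate growth series for
the slope study — sizes chosen so the full chain, including ~1,000
individual stroke renderings, completes in about a minute while every ring
retains hundreds of observations.

## Known limitations

* The half-perimeter rule carries an irreducible $O(\text{width})$ positive
  bias; for seedlings much shorter than ~50× their stroke width the
  relative error grows accordingly.
* The scalar per-ring factor corrects the *average* warp stretch in a ring;
  orientation anisotropy of the radial warp (radial strokes stretch
  ~3× more than tangential ones) and within-ring radius spread remain as
  ~1–2% residuals with 3 rings.
* Tilt must be supplied (by the oriented-box detector or ground truth);
  the package does not estimate it from imagery.
* Vitality shares depend on the normalisation strategy when treatment
  effects interact strongly with salt level; both strategies are reported
  for transparency.
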