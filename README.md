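# mpsquant

Automated detection and quantification of periodic protein nanostructures in
super-resolution fluorescence microscopy images.

Axons and dendrites carry a membrane-associated periodic skeleton (MPS): rings
of spectrin and actin spaced ~190 nm apart, resolvable by STED and STORM
nanoscopy but invisible to diffraction-limited imaging. `mpsquant` asks, for
every 1 µm² subregion of an image, a single statistical question: *how well
does this patch correlate with an ideal periodic pattern of known period?* The
answer — a masked two-dimensional Pearson coefficient maximized over pattern
orientation and phase — yields an objective, threshold-calibrated detection
decision per subregion, and from there batch-level summaries of MPS
**abundance** (fraction of neurite subregions containing the structure) and
**regularity** (mean correlation among detected subregions).

## Method overview

1. **Reference pattern.** A one-dimensional periodic profile
   `f(x) = A + B·sin^P(πx/T + φ)` extruded perpendicular to its axis, with
   even power `P = 6` and period `T = 190 nm` by default. Because the power is
   even, maxima are spaced `T` apart and the phase is identifiable only modulo
   π.
2. **Neuron discrimination.** A Gaussian blur (σ = 125 nm) followed by a
   relative threshold (mean + 0.65·std of the filtered image) separates
   neurite-occupied pixels from background. The rule is invariant to affine
   intensity rescaling.
3. **Segmentation and orientation.** The image is tiled into 1 µm² subregions.
   For each tile containing enough neurite pixels, the local neurite direction
   θ_N is pre-estimated from mask-boundary segments found by a progressive
   probabilistic Hough transform; tiles whose segments do not agree on a
   dominant direction (largest angular cluster ≤ 50%) are flagged ambiguous
   and excluded.
4. **Correlation scan.** The masked Pearson coefficient `R_P` between the tile
   and the rendered pattern is maximized over orientation (θ_N ± 20° in 1°
   steps) and phase (20 steps over 2π), using only neurite-mask pixels.
5. **Calibrated detection.** The detection threshold is the mean + 2.5·std of
   the best-`R_P` distribution on structure-free (null) tiles — a design
   chosen to cap false positives at ~1% under a Gaussian null. A tile is
   *detected* when its best `R_P` exceeds the threshold.
6. **Batch summaries and trends.** Per-tile records accumulate into abundance
   and regularity per image or condition; development time courses are fitted
   with a four-parameter logistic (reporting the half-height midpoint) or a
   saturating exponential.
7. **Simulator.** A four-step synthetic-image generator for validation:
   pattern rendered on a 1 nm raster, fluorophore labeling proportional to
   intensity plus a nonspecific fraction, a 40 nm FWHM Gaussian PSF on the
   20 nm output raster, and Gaussian background (10% relative std) with
   Poisson shot noise. Background level can be solved to hit a target
   signal-to-background ratio (SBR).

See [`docs/methods.md`](docs/methods.md) for parameter definitions, numerical
conventions, and known limitations.

## Worked example

### Python API

```python
from mpsquant import (PatternParams, SimulationConfig, MaskParams, HoughParams,
                      simulate, solve_background_for_sbr, discriminate,
                      estimate_direction, scan, phase_distance)

config = SimulationConfig(pattern=PatternParams(phi=1.0), theta_true=30.0, seed=7)
solved = solve_background_for_sbr(config, 8.0)   # background for SBR = 8
sim = simulate(solved)                           # 50x50 px, 20 nm/px tile

neuron = discriminate(sim.image, config.out_pixel, MaskParams())
est = estimate_direction(neuron.mask, HoughParams(seed=0))
res = scan(sim.image, neuron.mask, est.theta_n, config.pattern, config.out_pixel)
```

Actual output for this seed:

```text
realized SBR: 8.08   mask fraction: 0.352
direction valid: True   theta_N: 26.6 deg   cluster fraction: 0.80
best R_P: 0.681   best theta: 30.6 deg   best phi: 0.94 rad
phi error (mod pi): 0.058 rad
```

The scan recovers the true orientation (30°) within 0.6° and the true phase
(1.0 rad) within 0.06 rad, with a best correlation of 0.68 — far above the
typical null-tile level of ~0.14.

### Command line

```bash
mpsquant simulate --out demo/structured --seed 7 --sbr 8 --n-images 3
mpsquant simulate --out demo/null --seed 8 --sbr 8 --no-structure --n-images 3
mpsquant analyze --images demo/structured --out demo/results --threshold 0.2
```

`analyze` writes `records.csv` (one row per tile), `summary.json`, a
`detection_map.tif`, and a provenance JSON. Actual `records.csv` for the run
above (columns abridged):

```text
image_id  neuronal  direction_valid  theta_n_deg  best_rp  detected
sim_0000  True      True             30.5         0.678    True
sim_0001  True      True             28.4         0.705    True
sim_0002  True      True             29.3         0.717    True
```

and `summary.json` reports `abundance = 1.0`, `mean_rp_above = 0.700`.

Calibrating a threshold from labeled tiles (3 null + 3 structured from the
commands above) with `mpsquant calibrate` prints:

```text
threshold 0.2639 (null 0.1829 +/- 0.0324, n=3)
```

with zero false positives and zero false negatives on this (tiny) labeled
set; `mpsquant analyze --calibration calibration.json` then applies it. A
robustness curve of mean best `R_P` versus SBR is produced by
`mpsquant sbr-sweep --out sweep.csv`.

## Reproduction

Quantitative acceptance targets are recomputed from scratch by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which reports, for seed 1:

- `t1` (masked Pearson of an affine-rescaled copy of an image): `1.0`
  (exact affine invariance; n = 1),
- `t4` (relative variation of mean best `R_P` across SBR {3, 5, 8, 10}, 10
  replicates each): `2.76 %` (n = 40; stochastic — other seeds give 3–8%),
- `t5` (mean masked Pearson of 100 independent noise image pairs):
  `-0.0018` (n = 100; zero within Monte-Carlo error ~0.003).

The acceptance suite proper lives in `tests/test_acceptance.py` (one test per
release criterion; all randomness derives from pre-registered seeds). Two
criteria are currently not met under the fixed study conditions and are left
failing deliberately rather than tuned away; `docs/methods.md` analyses both
(orientation recovery at the 1° level is information-limited by the 400 nm
neurite width, and the synthetic SBR sweep is flatter than the ~10%
experimental figure).
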