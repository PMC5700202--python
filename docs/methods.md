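# Methods note

This note records the mathematical model, parameter choices, numerical
conventions, and known limitations of `mpsquant`. It is the reference for
anyone auditing the pipeline or extending it to other periodic structures.

## 1. Reference pattern model

The target structure is modeled as a one-dimensional periodic profile
extruded uniformly along the structure axis:

```
f(x) = A + B · sin^P(π x / T + φ)
```

with defaults `A = 0`, `B = 1`, `P = 6`, `T = 190 nm` — the values that
describe the spectrin membrane-associated periodic skeleton (MPS) of
neurites. Two consequences of the even power `P` matter in practice:

- **Period.** `sin^P` with even `P` repeats every half cycle of the
  underlying sine, so intensity maxima are spaced exactly `T` apart (190 nm),
  not `2T`. The fundamental period of `f` is `T`.
- **Phase identifiability.** `sin^P(u + π) = sin^P(u)` for even `P`, so the
  phase `φ` is identifiable only modulo π. The scan still sweeps `φ` over
  `[0, 2π)` (harmless redundancy, faithful to the published procedure), but
  all phase-recovery comparisons use circular distance with period π
  (`mpsquant.pattern.phase_distance`).

Rendering convention: a pixel with array index `(row, col)` has its center at
`((col + 0.5)·p, (row + 0.5)·p)` nm, where `p` is the pixel size. The pattern
coordinate is the projection `u = x·cosθ + y·sinθ` with θ measured
counter-clockwise from the column (x) axis and stored modulo 180°. During a
tiled scan, projections are taken in the *global* image frame (each tile
passes its `(row, col)` origin), so the fitted phase is comparable across
tiles. A `TabulatedPattern` hook accepts a numeric one-dimensional profile in
place of the parametric form.

## 2. Neuron discrimination

The image is smoothed with an isotropic Gaussian of σ = 125 nm (converted to
pixels, reflective boundaries) and thresholded at `mean + k·std` of the
smoothed image, with `k = 0.65` (midpoint of the 0.5–0.8 operating band).
Both statistics are taken over the whole image, which makes the mask
invariant to affine intensity rescaling — the same property the Pearson
correlation itself has.

Two documented consequences of this *relative* threshold rule:

- On a featureless background image it always marks the upper tail of the
  filtered noise (~26% of pixels at `k = 0.65`), so isolated speckle tiles
  can be flagged "neuronal". They are not *detected* — their correlation
  with the pattern stays far below threshold — and the pipeline's guarantee
  on pure background is therefore *zero detections*, not zero neuronal tiles.
- Under the `sin^6` pattern the inter-ring valleys genuinely fall below
  threshold, so footprint coverage at `k = 0.65` is ~73%; coverage ≥ 80% is
  reached at `k = 0.5`, the permissive end of the band. Detection is
  unaffected (masked pixels concentrate on the rings, which carry the
  signal).

## 3. Segmentation and orientation pre-estimation

Complete `L_sr = 1 µm` square tiles are taken row-major from the top-left
corner; partial border tiles are ignored. A tile enters analysis when at
least 20% of its pixels are neuronal (`min_fraction = 0.2`; permissive enough
to keep a thin neurite crossing corner-to-corner).

The local neurite direction θ_N is estimated from the *boundary* of the
neuron mask (mask minus its erosion): a progressive probabilistic Hough
transform (scikit-image, seeded and therefore deterministic) extracts line
segments with minimum length 25% and maximum gap 10% of the tile side. The
segment angles, taken modulo 180°, are grouped by sorting on the half-circle
and splitting at circular gaps larger than 15° (equivalent to single-linkage
clustering at that tolerance). The estimate is **valid** only when the
largest cluster holds more than 50% of the segments; its axial circular mean
(computed with angle doubling) is θ_N. Ambiguous tiles (crossing neurites,
too few segments) are excluded from analysis rather than analyzed with an
unreliable direction; a switch (`ambiguous_as_negative`) controls whether
they count in the abundance denominator.

## 4. Masked correlation scan

For each analyzed tile, the masked two-dimensional Pearson coefficient

```
R_P = Σ_M (I − Ī_M)(G − Ḡ_M) / sqrt( Σ_M (I − Ī_M)² · Σ_M (G − Ḡ_M)² )
```

is computed over neuronal-mask pixels `M` only, between the tile `I` and the
rendered pattern `G`, and maximized over a grid of θ ∈ θ_N ± 20° in 1° steps
and 20 phases covering 2π. Ties take the first maximum in scan order; tiles
whose mask fraction falls below 10% or whose masked variance vanishes are
reported degenerate (score 0 against constant patterns) rather than raising.
The per-θ maximum over φ is retained as a diagnostic curve. The inner loop is
vectorized over all phases for a fixed θ (the pattern for different phases
shares one projected-coordinate array), which keeps a full 41 × 20 scan of a
50 × 50 tile near 0.1 s.

Affine invariance (`R_P(I, aG + b) = R_P(I, G)` for `a > 0`) makes the
method insensitive to detector gain and offset; it is asserted to 1e-12 in
the acceptance suite.

## 5. Threshold calibration

The detection threshold is `mean + 2.5·std` (sample std, ddof = 1) of the
best-`R_P` values on structure-free null tiles, per modality. Under a
Gaussian null this caps the false-positive rate at Φ(−2.5) ≈ 0.62% < 1%,
which the acceptance suite verifies with 10⁶ Gaussian draws. False-negative
rates are reported against labeled positive tiles when available.

**Known limitation.** The statistic being thresholded is a *maximum* over a
41 × 20 (θ, φ) grid, and the null distribution of a maximum is right-skewed
(measured skew ≈ 0.65 on 1 400 simulated null tiles). Its measured exceedance
of the `mean + 2.5σ` threshold is 1.9% (95% CI 1.2–2.9%) — roughly three
times the Gaussian figure, though of the same order. Users who need a strict
1% guarantee should calibrate by empirical quantile (99th percentile of the
null best-`R_P` sample) instead; the `mean + kσ` rule is retained as the
published default.

## 6. Synthetic-image simulator

Four steps, each with its own random substream spawned from one seed
(`SeedSequence(seed).spawn(3)`), making images bit-reproducible:

1. **Ground truth** on a 1 nm raster: a straight neurite band (default width
   400 nm, length 1.4 µm, centered, at angle θ_true) carrying the pattern
   intensity, inside a 1 µm² field.
2. **Labeling**: the number of fluorophores is Poisson with mean
   `label_density × area`; positions are drawn with probability proportional
   to ground-truth intensity (specific, default ≈ 200 per tile) or uniform
   over the field (nonspecific, default 25% of the specific count), with
   sub-raster jitter.
3. **Imaging**: positions are binned to the 20 nm output raster, convolved
   with a Gaussian PSF of 40 nm FWHM (σ = FWHM/2.355), and scaled by 50
   detected photons per fluorophore.
4. **Noise**: Gaussian background with mean `bg_mean` and 10% relative
   standard deviation is added, and the whole image is Poisson-resampled
   (shot noise).

**SBR definition** (the literature rarely defines it numerically): the mean
of the top decile of in-mask pixel intensities divided by the mean intensity
outside the ground-truth mask. `solve_background_for_sbr` inverts this for
`bg_mean` using the average top-decile signal over 8 noiseless labeling
realizations — finite-labeling lumpiness raises the realized top decile ~35%
above the smooth expectation, and ignoring it put realized SBR far off
target. Realized SBR lands within ~11% of the request. Null (structure-free)
tiles are produced by `null_config`, which folds the pattern's mean intensity
into a uniform labeling density so total fluorophore counts match the
structured tiles.

Unstated-by-the-literature defaults (chosen once, before any acceptance
measurement, and never tuned): neurite width 400 nm, length 1.4 µm, ~200
specific fluorophores per tile, nonspecific fraction 25%, 50 photons per
fluorophore. These are the fixed *study conditions* for all validation
experiments.

## 7. Batch analysis and trends

`analyze_image` emits exactly one record per tile with its state
(`neuronal`, `direction_valid`, `best_rp`, `detected`, …); `summarize`
computes abundance (detected / analyzed), regularity (mean best `R_P` over
detected tiles), and a `uint8` detection map on the tile grid. Development
time courses are fitted with the four-parameter logistic
`y0 + (y1 − y0) / (1 + exp(−(x − x50)/τ))` — whose midpoint `x50` is the
half-height time — or a saturating exponential, via `scipy.optimize.curve_fit`;
non-convergence is flagged on the result, never raised.

## 8. Validation status and honest limitations

The acceptance suite (`tests/test_acceptance.py`, all seeds pre-registered)
passes on: oracle equivalence of the masked Pearson (1e-12), affine
invariance, 190 nm maxima spacing, the Gaussian-null 1% design criterion,
null decorrelation, phase recovery (within one φ step in ≥ 90% of seeds),
composite two-class classification (0/50 false positives, 0/50 false
negatives at the calibrated threshold), monotone SBR response, and logistic
midpoint recovery. Two clauses are currently **not met** under the fixed
study conditions and are deliberately left failing rather than tuned away:

- **Orientation recovery at the 1° level** (22/50 seeds within one 1° step at
  SBR 8; the suite's attainable assertion is 3°). Diagnostics show this is
  information-limited, not a defect: the curvature of `R_P(θ)` around the
  optimum scales with the squared extent of the stripes, i.e. the 400 nm
  neurite width. Widening the structure to 900 nm or quadrupling the label
  density yields 30/30 recovery within 1°, and centering the θ grid exactly
  on θ_true (instead of the Hough estimate, whose fractional offset
  misaligns the 1° grid) raises the count but not to the required level.
  Since the study conditions are fixed a priori, the strict clause stays red.
- **SBR-sweep relative variation** (2.8–8% across seeds versus the ~10%
  experimental figure). The synthetic sweep is *flatter* — more robust —
  than experiment, because the scan maximizes over (θ, φ) on a clean,
  straight, homogeneously labeled neurite; experimental variation includes
  labeling heterogeneity, drift, and curvature that the four-step generator
  deliberately does not model.

Out of scope by design: reproduction of any microscopy-data-derived numbers
(modality-specific thresholds 0.2/0.17, published false-negative rates,
half-height times in days in vitro, plateau levels), curved-neurite
simulation, drift/multi-frame effects, and 3D imaging.
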