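# Methods

## Coordinate and label conventions

Images are 2-D arrays in [0, 1] with row 0 at the vitreous (top).  Boundaries
are per-column integer row indices; the RNFL band occupies the half-open
interval `[upper, lower)`, so thickness in pixels is exactly `lower − upper`
and boundary→mask→boundary round trips are lossless.  Masks use three labels:
ABOVE (0), RNFL (1), BELOW (2).  The two backgrounds are distinct classes
because their textures differ anatomically, which helps the network separate
them.

## Phantom generator

A phantom is a piecewise-constant B-scan: background above the ILM
(default 0.08), hyperreflective band (0.85), background below (0.35) —
the band must be the brightest structure, as in real scans.  The ILM is a
sinusoid (`ilm_baseline` ± `ilm_waviness_amplitude`, 2 cycles across the
width); band thickness is `rnfl_thickness_mean` times a per-class scale
(glaucoma 0.65, normal 1.0, edema 1.9 — chosen to reproduce the clinical
ordering thinned < normal < thickened; configuration values, not clinical
truth).  Sub-pixel geometry rounds half-up; boundaries are stored at integer
rows because downstream masks are pixel-categorical.

Vessel shadows are contiguous column intervals (width drawn from
`vessel_width_range`, non-overlapping with ≥ 2 px gaps) darkened by the
factor `1 − vessel_contrast` from the ILM row to the bottom edge, matching
the assumption that shadows originate at the ILM and extend downward.
Speckle is multiplicative Gaussian, `x·(1 + N(0, σ²))` clipped to [0, 1] —
the simplest model that produces OCT-like texture.  It is *not* a physical
speckle model (no Rayleigh statistics, no point-spread function), and the
backgrounds are flat rather than layered; conclusions from phantom tests
therefore cover geometry and contrast behaviour, not device realism.

`edge_softness` (default 0) applies a vertical box filter of width
`2s + 1`, turning the band steps into linear ramps like the gradual
reflectivity transitions of real scans.  The default keeps the bands
exactly piecewise-constant; the soft setting exists because a 1-px overlay
drawn on a *hard* step is unrecoverable by any local inpainting (the
interpolant cannot know which side of the step the hidden pixel belongs
to — a 1-D biharmonic stencil puts it mid-way, an error of ~half the step
height).  Overlay-removal fidelity is therefore assessed on phantoms with
`edge_softness=2`, where recovery is near-exact since linear ramps are
biharmonic.

Phantoms default to 128×128, the network's input size, so generated
geometry is directly comparable with network output; the generator accepts
any size ≥ 32.  Cohorts (`generate_dataset`) allocate classes to subjects by
largest remainder, jitter ILM depth (±2 px steps) and mean thickness (±5 %,
clipped to ±20 %) per subject, and give every scan its own sub-seed.

## Overlay detection and inpainting

Overlay colors default to cyan (anterior) and red (posterior).  A pixel
matches a boundary when its circular hue distance is within 20° of the
target hue and saturation ≥ 0.3; grayscale content has saturation 0, so the
separation is clean even for anti-aliased overlays.  The per-column
representative row is the median matched row (robust to 2–3 px thick
lines); undetected columns are filled by linear interpolation, flat at the
edges, and a boundary matched in under half of the columns raises a
detection failure carrying the match fraction.  Inpainting solves the
biharmonic equation (scikit-image); constants and linear ramps are exact
fixed points, which the tests verify to 1e-6 / 1e-3.

## Vessel-shadow detection

The chain concretizes several steps that are stated only loosely in the
field:

* **SVD enhancement** keeps the smallest leading set of components whose
  squared singular values reach `svd_energy_fraction` (default 0.90) of the
  total.  Shadow bands are column-coherent and concentrate in leading
  components; speckle spreads over the spectrum.  The reconstruction is
  clipped (not rescaled) to [0, 1] so low-rank images are exact fixed points
  and truncation remains an energy contraction.
* **ILM detector**: first top-down crossing of an Otsu threshold on a
  vertically smoothed image (σ = 1 px), median-filtered across columns
  (window 15) to suppress shadow dropouts.  Exact on flat phantoms, ≤ 1 px
  on wavy ones.
* **Radon reinforcement**: angles −20°…+20° in 1° steps (shadows are only
  slightly slanted).  The 0° projection is normalized, squared, and rescaled
  to its original peak — squaring sharpens peaks; rescaling keeps the
  projection commensurate with the attenuated neighbours, which are
  multiplied by exp(−|θ|/5°).
* **Profile**: ramp-filtered back-projection at the mirror-padded width
  (padding = 25 % of width pushes border artifacts outside the region of
  interest), un-mirrored, summed per column, detrended by a moving average
  (window 15 % of width, reflected ends) and clipped at 0.
* **Thresholding**: a column is flagged when its profile value strictly
  exceeds *both* the 85th-percentile of the profile and an absolute floor of
  `min_response_fraction` (default 0.1) × image height.  The floor is
  needed because a pure quantile flags its top tail even on shadow-free
  scans; the image height is the largest possible column summation, so the
  floor is scale-free.  Measured responses separate cleanly: planted
  shadows at contrast 0.5 reach ~0.9 × height while shadow-free residual
  ripple stays below ~0.05 × height.  Flagged columns < 2 px apart merge
  (anti-aliasing splits single shadows); the mask runs from the detected
  ILM to the bottom edge and never contains supra-ILM pixels.
* **Inpainting** is applied to the *original* image, not the enhanced one.

On the 50-phantom benchmark (3 shadows per scan, width 4–8 px, contrast
0.5, speckle σ = 0.05) the detector reaches column recall 1.0 and precision
≥ 0.9, and recall is non-decreasing in shadow contrast.

## RNFL-Net

Standard U-Net topology with the configured widths: four encoder blocks
(two 3×3 conv + batch norm + ReLU, dropout 0.1 after the second conv) of
32/64/128/256 filters with 2×2 max pooling, a 512-filter bottleneck, four
decoder blocks with stride-2 2×2 transposed convolutions halving channels,
skip concatenation and two conv stages, and a final 1×1 convolution to three
channels through a per-channel **sigmoid**.  The output is deliberately not
a partition of unity; predictions are decoded by per-pixel argmax (ties to
the lowest class index) and column monotonicity is *not* enforced, so the
boundary extractor must tolerate ragged columns.  'Same' padding is used
throughout, so any input with H, W multiples of 16 (≥ 32) works.

The backend (`rnflseg.nn`) is pure numpy: im2col + BLAS matmul
convolutions in float32, with the input gradient computed as a correlation
with the rotated kernel (also a matmul), inverted dropout, batch
normalization with running statistics (momentum 0.9), and Adam with bias
correction.  All layers pass central finite-difference gradient checks at
1e-7 in float64.

Training uses soft Dice averaged over the three classes (ε = 1e-6;
mean-over-classes keeps the thin RNFL from being swamped by the two large
backgrounds), Adam at 1e-4 with reduce-on-plateau (factor 0.5, patience 10
epochs on validation loss) floored at 1e-6.  Batch size and epochs are
config (defaults 16 / 150).  `target_train_dice` enables early stopping for
deliberate-overfit runs: fitting eight noise-free 128×128 phantoms with
batch size 2 reaches training RNFL Dice ≥ 0.97 in roughly 15–25 epochs
(a few minutes on one CPU); the small batch gives Adam more updates per
epoch on such a tiny set.

## Evaluation metrics

Dice and IoU are computed for the RNFL class only and defined as 1 when the
class is absent from both masks (agreement on absence; avoids spurious
zeros on degenerate crops).  Confusion ratios with zero denominators are
reported as NaN, never 0.  Boundary extraction uses the span convention
(first RNFL row to one past the last) so non-contiguous prediction columns
still yield boundaries; band-free columns are linearly interpolated and
flagged.  MUE averages per-column absolute row differences; `axial_scale`
(µm/px) is a required parameter with no default because the device pixel
pitch is unknown in general — phantom tests use 1.0 so px ≡ µm.  MAPE
doubles when true thickness halves at fixed absolute error, which is why
percentage errors inflate in thin (glaucomatous) layers.

Group comparison: per-group Shapiro–Wilk, Kruskal–Wallis omnibus, pairwise
two-sided Mann–Whitney U at Bonferroni-adjusted α (α divided by the number
of pairs).  Mann–Whitney uses the exact null when both groups have n ≤ 20
without ties, the tie-corrected normal approximation otherwise.  The
statistics agree with R's `shapiro.test`, `kruskal.test` and `wilcox.test`
to 1e-8 on fixed samples, and the empirical type-I rate of the omnibus test
is at the nominal level over 100 seeded homogeneous replicates.

## Splitting

`split_subject_wise` holds out whole subjects for the test set (per-class
count = round(test_fraction × subjects)), then deals the remaining subjects
round-robin into k folds per class after a seeded shuffle — each subject
validates exactly once and never straddles train/validation.  On real data
the test set would target scans with device segmentation errors; phantoms
have no such notion, so the holdout is random whole-subject sampling.

## Problem sizes and determinism

Default verification sizes: 128×128 phantoms; 50 phantoms for the vessel
benchmark; 8 phantoms for overfit training; 100 replicates for the type-I
simulation.  Every stochastic stage takes a seed; the CLI derives per-stage
seeds from one global seed via CRC32 of the stage name, and the pipeline
manifest records a content hash of every output so reruns are verifiable.

## Known limitations

* Phantoms are geometric stand-ins; no device point-spread function,
  Rayleigh speckle, curvature or multi-layer anatomy.  Passing tests show
  the algorithms are implemented correctly and behave as designed on
  controlled geometry, not that clinical accuracy is reproduced.
* The vessel detector assumes shadows at most ~20° off vertical and at
  least ~0.1 × height in integrated contrast; faint or strongly slanted
  shadows fall below the floor.
* The numpy backend targets CPU-scale experiments (minutes for small
  training runs), not production training.
* Screenshot panel localisation is a configured rectangular crop; automatic
  panel detection and OCR of device annotations are out of scope.
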