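# Methods

## Segmentation model

The segmenter is a U-Net-style fully convolutional network: `depth`
encoder stages of (3×3 convolution, ReLU, 2×2 max-pool), a bottleneck
convolution, and mirrored decoder stages of (nearest-neighbor ×2
upsampling, concatenation with the encoder skip tensor, 3×3
convolution, ReLU), closed by a 1×1 convolution emitting two-class
scores per pixel that a softmax turns into a spheroid-probability
map. Channel width doubles per stage from `base_channels`.

The network is implemented directly on NumPy with hand-written
backward passes. Tensors are float32 channels-last (N, H, W, C);
each 3×3 convolution is computed as a single GEMM of the zero-padded
frame against all nine kernel taps followed by shifted slice-adds,
which avoids the im2col gather and is what makes CPU training
practical (a 128×128 epoch over 120 augmented images takes a few
seconds on one core). Gradients of every layer and loss are verified
against central finite differences in the test suite.

Weights use He initialization from a seeded generator; inputs are
8-bit images normalized by division by 255. Inference pads
reflectively to the stride multiple 2^depth and crops afterwards, so
arbitrary image sizes are accepted; probability maps produced at
reduced resolution are bilinearly upscaled to the native grid
*before* thresholding, so every metric lives on the native pixel
grid.

### Training recipe

* **Losses.** Dice (region-based, default), cross-entropy and focal
  (distribution-based). Dice smoothing ε = 1.0 in pixel-count units;
  probabilities are clipped to [1e−7, 1 − 1e−7] before logs. Focal
  with γ = 0 reduces exactly to cross-entropy.
* **Optimizers.** Adam (default) and RAdam+Lookahead (k = 5,
  α = 0.5), both implemented from their published update rules. The
  choice matters little for this architecture; both are exposed
  because they are the two configurations practitioners compare.
* **Learning rate.** The 1-cycle policy: one linear ramp from the
  lower to the upper bound over the first half of all steps and back
  over the second half. Default bounds (1e−3, 1e−2) suit the compact
  network; there is no automatic range test — bounds are explicit
  configuration.
* **Early stopping.** After every epoch the *postprocessed* mean
  Jaccard distance on the validation set is computed (threshold →
  largest component → JCD), i.e. exactly the quantity the
  segmentation is judged by rather than the raw loss. Training stops
  after `patience` (default 10) consecutive non-improving epochs and
  the best-epoch weights are restored.
* **Leakage guard.** Spheroid identity is the unit of splitting; a
  spheroid id present in both the training and validation sets aborts
  before the first epoch. Images of one spheroid are time-series
  frames and strongly correlated, so image-level splits would leak.
* **Augmentation.** Each training image is transformed exactly once
  by one uniformly chosen transform from {vertical flip, horizontal
  flip, 180° rotation}, doubling the set. The copy is fixed, not
  re-drawn per epoch. These transforms preserve the rectangular frame
  (no border extrapolation) and are valid because spheroids have no
  preferred orientation.
* **Batch size** defaults to 2, matching common practice for
  full-resolution microscopy training under memory pressure.

## Postprocessing

Probability maps are binarized at an inclusive threshold of 0.5 (a
pixel at exactly 0.5 is spheroid). Foreground is labeled with
8-connectivity (4-connected background), components numbered in
raster-scan order of their first pixel. The largest component is the
spheroid — consistent with assay practice, where the largest
regrowing body determines relapse; ties are broken by lowest label.
Its outer border is traced by Moore-neighbor border following
(clockwise neighborhood scan from the backtrack direction, start at
the topmost-leftmost pixel, terminate on re-entering the start),
yielding a closed polygonal chain of pixel-center coordinates whose
consecutive points are 8-neighbors. Interior holes are ignored; only
the outer contour contributes to the perimeter. No speckle
suppression is applied by default (`min_area = 0`), faithfully
keeping every thresholded component; a configurable minimum area is
available because real probability maps can speckle.

The Otsu baseline thresholds the inverted 8-bit intensity (the
spheroid is dark on a bright background) and runs the identical
component/contour chain, so model-vs-baseline comparisons differ only
in how the foreground was proposed.

## Evaluation metrics

Per image, predicted set *P* (largest component) against target *T*:

* **JCD** = 1 − |P∩T|/|P∪T|: relative area error, 0 = perfect,
  1 = disjoint. Human raters consider JCD below ~0.2 acceptable.
* **RDD, RCD** = |c_P − c_T|/c_T for mean diameter and circularity:
  the errors that actually propagate into growth curves.
* **Δr** = √((|P∪T| − |P∩T|)/π + d_T²/4) − d_T/2: the thickness an
  annulus with the mismatched area would have around a circle with
  the target's area. Surplus (P∖T) and missing (T∖P) areas are summed,
  not cancelled, so a shifted prediction with a perfect diameter still
  shows its full boundary error. Note that for strictly nested disks
  Δr is slightly *below* the radius gap because the mismatched annulus
  is spread at a radius ≥ the target's.
* **Case taxonomy.** JCD = 1 (largest component disjoint from the
  target) marks the image *invalid*: it counts toward the invalid
  spheroid fraction (ISF) and RDD = RCD = 1 by convention, with Δr
  computed against the empty prediction so summaries stay well
  defined. Extra components alongside a valid largest one mark the
  image *ambiguous* (counts to ASF); an image whose largest component
  fails entirely counts to ISF only. ISF and ASF are reported with
  the binomial standard error √(p(1−p)/n).
* **Degenerate shapes.** Components whose chain has fewer than 3
  points carry no perimeter; their circularity is defined as 1.0 and
  flagged. Circularity of digitized shapes may exceed 1 slightly
  (chain-length underestimate on small rasters); values are reported
  as computed, not clipped.

Interobserver agreement uses per-image pairwise JCD tables (R raters
→ R(R−1)/2 pair columns, lexicographic). The Friedman statistic uses
within-block mean ranks with the standard tie correction and
chi-square asymptotics (adequate at the block counts used here;
a fully tied table reports statistic 0). Dunn's post hoc z uses the
mean-rank standard error √(k(k+1)/(6n)) with two-sided normal
p-values Bonferroni-multiplied by the number of pairs and clipped at
1.

## Synthetic data

The generator renders what treated-spheroid brightfield frames look
like, not their optics: a multiplicative transmittance field under a
linearly ramped illumination with additive Gaussian noise (noise
attenuated with the transmittance), quantized to 16 bits.

* **Spheroid:** a disk whose boundary radius is perturbed by random
  low-order angular modes (RMS amplitude `boundary_irregularity`,
  default 0.08) and whose attenuation rises from 0.35 at the rim to
  0.70 at the center (thickness proxy).
* **Debris:** an annulus out to `debris_extent_factor` × spheroid
  radius (default 2.5) carrying smoothed-noise texture (correlation
  length `debris_graininess`, default 6 px) scaled by
  `debris_opacity` (default 0.5) with a radial falloff. At high
  opacity, debris patches are darker than the spheroid rim and the
  darkest pixel of a frame regularly lies *outside* the target — the
  property that defeats thresholding. Debris never enters the target
  mask.
* **Background:** level 1300 with spread 130 in 16-bit units and a
  ±5% illumination ramp — a deliberately narrow band (<10%) of the
  16-bit range, as microscope frames use.
* **Geometry:** native conditions are 1,300×1,030 px at 2.04 µm/px
  with spheroid diameters 200–500 µm. The desk-scale configuration
  used by tests, examples and the acceptance script keeps the same
  spheroid-to-frame proportions at 128×128 px and 4 µm/px with
  100–200 µm spheroids. Nominal diameters are drawn from the inner
  90% of the configured range so the rendered equivalent diameter
  stays inside it despite boundary perturbation; touching double
  spheroids (probability 0.05) intentionally enlarge the target
  beyond the single-spheroid range.
* **Time series:** all frames of one spheroid share geometry; the
  diameter grows by a per-step factor drawn from (1.0, 1.08).
* **Raters:** simulated boundary jitter displaces the target
  boundary by a smooth random radial field (low-order angular modes,
  RMS amplitude in px) via thresholding of the signed distance
  transform; zero amplitude reproduces the target exactly.
* **Reproducibility:** every sample derives from a counter-based
  stream seeded by (dataset seed, sample index), so any single image
  is regenerable in isolation.

What the generator does *not* emulate: diffraction and defocus,
semi-transparent or incompletely formed spheroids, imaging artifacts
(dust, vignetting beyond a linear ramp), or debris whose texture
statistics are matched to real cultures — no quantitative debris
statistics exist to match. Passing the training-recovery test
therefore shows the pipeline can learn to separate a dark body from
darker-textured clutter under realistic intensity statistics; it does
not certify accuracy on any particular real cell line or microscope.

## Numerical and design choices

* 16→8-bit conversion is per-image min–max with round-half-up; a
  constant frame maps to all zeros (the rescale is undefined there,
  zero is the conservative choice). The conversion is idempotent on
  its own output.
* Images resize bilinearly, masks nearest-neighbor; resized
  dimensions are round(dim × factor) with a floor of 8 px.
* Splits randomize over spheroid ids with largest-remainder
  apportionment of the id counts; every non-empty fraction receives
  at least one id.
* Contour pixels are pixel centers, not crack edges; this biases the
  perimeter of digitized disks about +5% relative to 2πr, within the
  documented [0.9, 1.12] band, and is reported uncorrected.
* The perimeter includes the closing segment of the chain.
* Checkpoints are NumPy `.npz` archives (architecture metadata plus
  parameter arrays).

## Problem sizes

The test suite and acceptance script use the desk-scale conditions:
100 spheroids (60 train / 20 val / 20 test by id) at 128×128, up to
40 epochs, and 50 heavy-debris frames (`debris_opacity` 0.85) for the
baseline comparison. These sizes were chosen so a full from-scratch
reproduction — data generation, training, evaluation — completes in
minutes on a single CPU core while leaving the training problem
non-trivial (the Otsu baseline fails on it by a wide margin).

## Known limitations

* Only the outer contour is traced; hole-aware topology and
  sub-pixel smoothing are out of scope.
* On pathological masks with one-pixel spurs at the start pixel, the
  border walk may close early; the shapes this package produces and
  evaluates (thresholded blobs) do not trigger this in practice.
* The Friedman p-value is asymptotic; no exact permutation variant.
* No pretrained encoders ship with the package; `encoder_id` is a
  hook for locally available weights, and transfer learning is off
  by default.
* The CLI covers the single-spheroid-per-image workflow; multi-
  spheroid reporting beyond the ambiguous flag is not implemented.
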