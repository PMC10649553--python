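# Methods

## Problem and pipeline

The package measures vascular calcification on contrast-enhanced CT
angiography of the abdominal aorta and lower-extremity arteries. The
pipeline has two stages. First, a convolutional encoder–decoder network
assigns each pixel of every transverse slice a probability of belonging
to the arterial system; thresholding at 0.5 gives a binary vessel mask.
Second, the mask is multiplied voxelwise with the 8-bit image, voxels
with intensity strictly above 145 inside the masked region are counted
per slice over a half-open anatomical slice range, and the total count
is converted to a volume by the voxel volume dx·dy·dz. The start of the
scoring range corresponds to an anatomical landmark (the slice just
below the left renal artery in the clinical protocol) and is a required
input, not something the pipeline detects.

The intensity threshold of 145 is on the 0–255 scale. It was originally
established by independent raters as the value that captures wall
calcification without selecting contrast-filled lumen; the package
treats it as a constant of the protocol, overridable per run.
"Exceeds the threshold" is implemented as a strict inequality; an
`inclusive` flag covers the ≥ reading. An Agatston-style minimum
component-area filter (8-connected 2-D components below a given mm²
discarded before counting) is implemented but off by default: the
automated protocol applies plain thresholding, and the 1 mm² rule
belongs to the clinical Agatston score in Hounsfield units, which this
package deliberately does not reproduce (no density weighting, no bone
subtraction).

## Segmentation network

The architecture is a U-Net with a residual-block encoder:

- a strided 3×3 stem and four residual stages, each halving resolution
  (inputs must be divisible by 2⁵); grayscale input is duplicated to
  three channels inside the network, matching the convention of RGB
  encoders;
- four skip connections (stem + first three stages) into a five-block
  decoder; each decoder block does nearest-neighbour ×2 upsampling,
  concatenation with the matching encoder feature, then two
  conv → batch-norm → ReLU stages; a 1×1 convolution and sigmoid produce
  the probability map.

The default configuration is a reduced, architecture-isomorphic variant
(8 base channels, one block per stage, ≈ 90k parameters) that trains on
one CPU in under a minute at the problem sizes used here; the 34-layer
family configuration (`base_channels=64, blocks_per_stage=(3,4,6,3)`) is
available but impractical without accelerator hardware. Pretrained
encoder weights are exposed only as an explicit unavailable hook: all
runs here start from seeded He-normal initialisation, so results measure
the architecture and training recipe, not transferred features.

Because no deep-learning framework is part of the dependency set, the
network runs on a small reverse-mode autograd engine over numpy arrays
(`vasccalc.nn`): im2col convolution, batch normalisation (batch
statistics in training, running averages in eval), ReLU/sigmoid,
nearest-neighbour upsampling, channel concatenation and Adam. Gradients
of every structured operation are verified against central finite
differences in the test suite. All computation is float32.

## Loss and training

The loss is `bce_w·BCE + jaccard_w·(1 − soft-IOU)` with weights 1:1
(unstated in the reference recipe; configurable). Soft-IOU uses
Σ p·t as intersection and Σp + Σt − Σp·t as union, so on hard {0,1}
predictions the Jaccard term equals 1 − TP/(TP+FP+FN) exactly; when both
target and prediction are identically empty the term is defined as 0.
BCE clamps probabilities to [1e-7, 1 − 1e-7].

Training uses Adam at learning rate 1e-3, batch size 15. The reference
recipe runs 100 epochs; the desk-scale default is 20–30, which suffices
for the phantom task. Validation IOU (slice-level, hard masks at 0.5) is
recorded each epoch, and the checkpoint with the best validation IOU is
returned — no early stopping. Data splitting is always patient-level:
`make_folds` partitions patient ids into k test folds of given sizes
(e.g. 11 patients as 3+3+3+2 over four folds), deterministically in list
order, and the training loop holds out the last training patient as
validation. "Pretrain then fine-tune per fold" readings of the recipe
are ambiguous; each fold trains independently from the same seeded
initialisation, the cross-validation-sound interpretation.

## Augmentation

Training-time augmentation applies, jointly to image and mask, the
geometric transforms horizontal flip (p = 0.25), grid distortion
(p = 0.70; 5×5 control grid with per-cell displacement limit 0.3, a
pinned default) and downscale–rescale (scale uniform in 0.60–0.90,
p = 0.30; the image is resampled bilinearly, the mask with nearest
neighbour so it stays binary). Photometric transforms — histogram
equalisation, CLAHE with clip limit 0.4, box blur with kernel sampled
uniformly from odd sizes 3–7, brightness/contrast jitter (±0.2) — are
applied to the image only: equalising or jittering a {0,1} mask is
meaningless, so "applied to both" is interpreted as geometric-only for
masks. Saturation/hue jitter is a no-op on single-channel CT data and is
omitted. Per-transform application probabilities not stated by the
recipe (equalisation, CLAHE, blur, jitter) default to 0.5. Augmentation
multiplicity defaults to 3 copies per original. The empirical
application rates are property-tested against their binomial bands.

## Phantom generator

The generator emulates the statistical structure of lower-extremity CTA
at desk scale:

- geometry: square slices (default 128×128 in the spec of a full
  phantom; the study-condition cohorts use 64×64 for CPU speed),
  default 1 mm isotropic spacing (scanner spacing is a convention here,
  not a measured value); one vessel per volume as a disk whose centre
  drifts smoothly (seeded sinusoid, amplitude 8% of the frame) and whose
  outer radius (10–14% of the frame) may taper distally;
- intensities (8-bit): background 40, non-calcified wall 90, lumen 130
  — bright against background but below the 145 threshold, as the
  threshold was defined to exclude contrast-filled lumen — calcified
  arcs 200–245, bone confounders 200. Calcifications are annulus
  sectors embedded in the wall (validated to lie inside it); bones are
  disks validated not to touch the vessel so that truth stays clean
  while still providing an intensity-overlapping distractor;
- corruption: additive Gaussian noise (σ = 5 in the study conditions)
  truncated to [0, 255], and phenomenological artifacts — `no_contrast`
  pulls non-calcified vessel intensity toward the background median,
  `metal_streak` overlays saturated radial streaks from the brightest
  extravascular point, `stent` paints a hyperintense annulus on the
  vessel boundary. Artifacts and noise never alter the truth masks.

Rasterisation rule: a voxel belongs to a region iff its integer centre
lies inside the analytic region — no anti-aliasing — so the true calcium
volume (count × dx·dy·dz) is exact and independent of rendering; this is
verified against an independent double-loop point-in-region oracle. The
generator does **not** simulate CT physics (no Radon transform, beam
hardening or realistic streak artifacts), multi-vessel anatomy,
bifurcations or sub-patellar small vessels. Passing phantom tests
therefore demonstrates that the implementation is correct and that the
architecture can learn this class of segmentation; it does not certify
clinical accuracy on patient CTAs, which are unavailable.

## Intensity-scale conversion

`hu_to_8bit` maps a Hounsfield window (lo, hi) linearly onto [0, 255]
with clipping and round-half-up; the default window is the volume's own
min–max (the common ImageJ-style conversion), since the original manual
protocol does not state its window. A constant volume maps to zeros.
The map is monotone non-decreasing for every window, a property the
tests check, because the calcium threshold must respect intensity
ordering.

## Study conditions and problem sizes

The learning checks train on 40 slices (five 8-slice, 64×64 phantoms,
noise σ = 5, one further phantom as validation) for 30 epochs and
evaluate on eight independent noisy phantoms; these sizes are the
package's desk-scale analogue of the original 11-patient training set of
512×512 slices. Under these conditions the network reaches held-out mean
per-slice Dice ≈ 0.84–0.90 and automated calcium volumes with
MAPE ≈ 3–6% and r² ≈ 0.98–1.0 against closed-form truth across seeds
(computed by `scripts/acceptance.py`). These figures characterise the
phantom task — which is easier than patient data — and are read as
bounds-style checks (Dice ≥ 0.8, MAPE ≤ 15%, r² ≥ 0.9), not as a
reproduction of clinical accuracy.

## Numerical choices and degenerate cases

- Dice and IOU of two empty masks: 1.0 (perfect agreement on absence);
  per-slice outputs flag nothing special — annotated clinical slices
  always contain vessel, so this is a phantom-edge convention.
- APE/MAPE raise on zero reference values; r² raises when the reference
  is constant (TSS = 0).
- Binarisation of probabilities uses strict `>` at threshold 0.5
  (exposed as a flag); thresholded counting uses strict `>` at 145.
- Slice indexing is 0-based, axis order (slice, row, col), ranges
  half-open; one convention everywhere.
- Rounding to integer intensities is round-half-up throughout, pinned
  for bit-exact cross-run behaviour.
- Known divergence: the reference analysis prints a manual/automated
  pair (7892, 7707) as APE 2.04%, but the APE formula gives 2.344%; the
  implementation follows the formula and the discrepancy is recorded,
  not matched.

## Limitations

- The phantom is phenomenological; no claim transfers to patient CTAs
  without retraining and validation on real data.
- One vessel per volume; no bifurcations, adjacent small arteries or
  incomplete contrast filling along the vessel.
- The full-size encoder is untested at scale on CPU; only the reduced
  configuration is exercised by the test suite.
- DICOM series assembly is out of scope; NIfTI and PNG stacks are the
  supported containers.
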