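# Methods

## Model

The segmentation model is a semantic U-Net with a single foreground output
channel. The encoder consists of `depth` downscaling blocks; each block is
two convolutional sub-blocks (zero-padded 3×3 convolution → batch
normalisation → leaky ReLU, negative slope 0.01) followed by 2×2 max
pooling. The number of kernels starts at `base_channels` (default 32) and
doubles with each downscaling block, capped at `channel_cap` (default 512);
the bottleneck continues the doubling rule at the cap. The decoder mirrors
the encoder with separable bilinear 2× upsampling (half-pixel centres),
concatenation of the matching encoder skip, and two conv sub-blocks that
halve the channel count. A 1×1 convolution produces a logit map; the
sigmoid of it is the foreground probability.

With the default 7 downscaling blocks, one pixel of the deepest feature map
spans 2⁷ = 128 input pixels per axis. This *cumulative downsampling
factor* is what the package reports and what `scripts/acceptance.py`
measures by pushing a probe image through the constructed encoder. It is
distinct from the *effective receptive field*, which additionally grows
with every 3×3 convolution and therefore exceeds 128 pixels; the two are
often conflated in informal descriptions of U-Nets.

Design choices the architecture description leaves open, fixed here:

- conv → batch-norm → activation ordering (the most common U-Net
  convention);
- leaky-ReLU slope 0.01, configurable;
- input intensities are divided by the container maximum (255 for 8-bit) to
  [0, 1]; the constant is stored in checkpoints so they stay portable;
- inputs whose sides are not multiples of 2^depth are reflection-padded
  (reflection avoids border artifacts in microscopy tiles) and the output
  cropped back; images smaller than 2^depth per side are rejected;
- inference always uses batch-norm running statistics, so repeated
  predictions are bit-identical.

The network, backpropagation and the Adam optimiser are implemented
directly on NumPy arrays (channels-last, float32); convolutions are one
im2col copy plus a single BLAS matrix product per layer, and their backward
passes are two further products plus a fold-back accumulation. Gradient
correctness is established against central finite differences in float64.

## Training

The loss is pixel-mean binary cross entropy with a multiplicative weight
`w` on the foreground term, `−mean(w·y·log p + (1−y)·log(1−p))`. The
weight boosts sparse foreground (e.g. few, large nuclei); the weighted
class is the positive one because only that choice makes large weights
(up to 200 in the retraining grids) meaningful. The gradient is computed
from logits in a numerically stable fused form.

Augmentations are horizontal/vertical flips and 90°-multiple rotations
applied identically to image and mask; 90° steps avoid interpolating label
masks (arbitrary-angle rotation is available behind a flag, with
nearest-neighbour mask resampling). An optional blur/sharpen augmentation
perturbs the image only. Training samples are random square crops whose
side must be a multiple of 2^depth.

Optimisation uses Adam with default moments (β₁ = 0.9, β₂ = 0.999); no
learning-rate schedule. Checkpoints are evaluated on the validation set
every epoch for runs up to 100 epochs, every 10 epochs beyond (both
overridable); the selection criterion is either the image-wise mean adapted
F1 at τ₁ (general protocol) or the mean object IOU of large cells above the
physical size cutoff (large-nucleus retraining protocol). The checkpoint
with the highest score is returned; ties go to the earliest. A NaN loss
aborts with a diagnostic. `grid_search` trains every learning-rate ×
loss-weight × replicate combination and reports every cell's score; the
returned model is the report argmax.

## Postprocessing

Probability maps are thresholded at 0.5 with a strict inequality (a pixel
exactly at the threshold is background). Connected foreground components
with area strictly below `min_object_px` are removed first; background
components (under the dual connectivity) that do not touch the image border
and have area strictly below `min_hole_px` are then filled. The
objects-before-holes order follows the order the steps are conventionally
listed in; `clean` is idempotent at fixed parameters. Foreground
connectivity defaults to the 8-neighbourhood. Instance labels are assigned
by connected components in raster order of each component's first pixel.

The optional run-time mask adjustment dilates or erodes each label with a
disk of radius |r|. Dilation is per-label with contested pixels assigned to
the label with the nearer centroid (ties to the lower label), so labels can
never merge; erosion can delete labels entirely.

## Evaluation metrics

Object-wise IOUs are exact integer intersection/union counts per
overlapping (ground-truth, predicted) object pair. Matching uses two IOU
thresholds, τ₁ = 0.6 and τ₂ = 0.1 by default. Per ground-truth object,
with precedence top-down: true positive if some prediction exceeds τ₁
(for τ₁ ≥ 0.5 at most one can — two sets cannot each share a strict
majority of a third — and this is asserted; below 0.5 a greedy max-IOU
assignment applies, with a warning); *split* if more than one prediction
falls in (τ₂, τ₁]; *inaccurate mask* (IA) if exactly one does; otherwise
false negative. False positives are predictions whose best IOU is ≤ τ₂;
merges are predictions with more than one ground-truth partner in
(τ₂, τ₁]. TP + FN + IA + splits always equals the number of ground-truth
objects.

The conventional F1 counts every object unmatched at τ₁ as an error:
`2TP/(2TP + (n_pred−TP) + (n_gt−TP) + ε)`. The adapted F1 counts each
IA or split ground-truth object once and drops the double FP/FN penalty:
`2TP/(2TP + FP + FN + IA + splits + ε)`. Because FN + IA + splits =
n_gt − TP and the τ₂-based FP never exceeds n_pred − TP, the adapted
denominator is never larger, so adapted ≥ conventional at equal τ₁ —
verified property-wise, alongside exact agreement with a brute-force
oracle that enumerates all pixel overlaps and applies the category rules
literally.

Further choices where the rules are silent: a ground-truth object with a
>τ₁ partner *and* extra (τ₂, τ₁] slivers is still a TP (a well-segmented
nucleus is not penalised for a sliver of a neighbouring prediction);
predictions whose best IOU lies in (τ₂, τ₁] incur no separate FP in the
adapted score (they are the counterpart of an error already counted once);
ε = 1e−8 and is always added, so an image with no ground-truth and no
predicted objects scores 0 — such images are flagged `empty_agreement` in
reports rather than averaged silently.

Dataset scores come in two conventions: `avg` is the unweighted mean of
image-wise scores (this is F1avg0.6 for the adapted metric at τ₁ = 0.6) and
`agg` computes the metric once on summed contingency tables. Split and
merge rates are reported per 50 ground-truth (respectively detected)
nuclei, mean ± s.d. across images; images with a zero denominator are
excluded from the respective rate and counted. Size-stratified object IOU
assigns each ground-truth object its best-partner IOU (0 when none
overlaps) and averages per stratum, with *large* defined as pixel area ×
(pixel size)² strictly above 750 μm².

## Trace quantification

Traces are per-cell time series of mean intensities with a stimulation
time. Missing timepoints (missing masks) are replaced by the mean of the
observed values of that trace — the flags are kept for provenance, and a
neighbour-interpolation option exists. Resampling linearly interpolates
onto a uniform grid starting at the first timepoint (default 7-minute
step) and never extrapolates.

Two normalisations: (1) divide each cell's trace by its pre-stimulation
mean, then min-max rescale all values of an experiment jointly to [0, 1];
(2) divide the nuclear trace pointwise by the whole-cell trace, then by the
pre-stimulation mean of the ratio, making the pre-stimulation mean exactly
1. Both baseline divisions are invariant to rescaling raw intensities.
Degenerate inputs (zero baseline, constant experiment, zero whole-cell
values) raise errors naming the offending cell.

Trace dissimilarity D is the plain Euclidean norm of the value difference
on the common time grid — traces of different lengths are compared on
their overlap and the overlap length is available to report alongside D;
no length normalisation is applied. Marker status thresholds are computed
from the pre-stimulation baseline of the normalised whole-cell trace:
Ly6C at mean + 5·s.d., CD115 at 3·mean. The s.d. uses the sample
convention (ddof = 1, as in R's `sd`, the environment such calls are
conventionally made in); the population convention is available via
`sd_ddof=0`. A cell is positive iff any post-stimulation value exceeds the
threshold; the threshold is returned for audit. The final manual
confirmation step of marker assignment is out of scope.

## Synthetic data

The generator emulates what the pipeline actually has to cope with, not
optics: cells are radially perturbed ellipses (low-order Fourier modes;
a fraction of cells get stronger protrusions, emulating pseudopodia) whose
radii are log-uniform over (4, 14) px so areas span roughly an order of
magnitude; objects are placed without overlap and with a margin so ground
truth is unambiguous. The bright-field render gives mid-grey background,
slightly darkened textured interiors, a bright halo ring at boundaries,
additive Gaussian noise and a multiplicative illumination gradient; a
nuclear-marker render provides the high-contrast channel ground truth
would be derived from. A dense mode quadruples the cell count at reduced
margin for undersegmentation stress-tests. One global seed drives a
per-image stream (`seed + index`), so datasets extend without reshuffling
existing images, and regeneration is byte-identical.

What passing on this generator does *not* show: robustness to real optical
artifacts (defocus, debris, uneven illumination beyond a linear gradient),
to touching or overlapping nuclei, or to the domain gap between
fluorescence-derived and manually curated ground truth. The synthetic
benchmark demonstrates that the implementation can learn and be evaluated
end-to-end, not that a model trained here transfers to a microscope.

Mask corruptions (drop, shift, split, merge, boundary jitter) return the
corrupted mask together with the contingency expected under the matching
rules, computed directly from pixel overlaps with plain loops —
independent of the vectorised evaluation path, which is tested against
these fixtures and against a second oracle written in the test suite.

## Desk-scale benchmark

`nucseg.benchmark.run_desk_scale_benchmark` trains the full-depth
(7-block, base-32) U-Net from scratch on 32 synthetic 256×256 images for
16 epochs on random 128×128 crops (batch 4, Adam, lr 2e−3), selects the
checkpoint by validation adapted F1 on 8 further images (evaluated every
4 epochs), and reports F1avg0.6 on 8 held-out images after standard
postprocessing (threshold 0.5, min object/hole 10 px). These problem sizes
keep a single-CPU run in the minutes range; the validation score saturates
well before the epoch budget on this task.

## Known limitations

- The NumPy network trains on CPU only and is not competitive in speed
  with GPU frameworks; it exists to make the full pipeline self-contained
  and exactly reproducible.
- Touching nuclei are resolved only by connected components — no watershed
  or seeded splitting — matching the semantic-plus-components design.
- The conventional-F1 comparison below τ₁ = 0.5 depends on a greedy
  max-IOU choice that other implementations may make differently.
- Reported Euclidean trace distances are not length-normalised; compare
  only at equal grid lengths.
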