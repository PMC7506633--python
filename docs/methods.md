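# Methods

## Model

`wavecnn` implements a spectral–spatial convolutional classifier for
histopathology patches. The input image is decomposed by a multilevel 2D
Haar wavelet transform, and the subband stacks of levels 1–4 are injected
into a convolutional trunk by channel concatenation at matched resolutions,
so the network sees both learned spatial features and fixed multiresolution
spectral features.

### Haar filter bank

One decomposition level correlates each channel with four 2×2 kernels over
non-overlapping 2×2 blocks (stride 2, top-left anchored, no padding — even
input sizes are required and odd sizes are rejected rather than padded):

    W_LL = [[ 1,  1], [ 1,  1]]     W_LH = [[-1, -1], [ 1,  1]]
    W_HL = [[-1,  1], [-1,  1]]     W_HH = [[ 1, -1], [-1,  1]]

Three normalizations are exposed because the two standard conventions (the
integer filter bank above versus the orthonormal scaling used in transform
theory) differ by constant factors:

* `raw` — the ±1 kernels verbatim; on the block `[[1,2],[3,4]]` the four
  responses are 10, 4, 2, 0.
* `orthonormal` — kernels × 1/2; the flattened kernels form an orthonormal
  basis of R⁴, so each level conserves energy (Parseval). **Network
  default**: keeps activation scale stable across levels.
* `average` — like `orthonormal` but W_LL rescaled to entries 1/4, making
  the LL subband exactly 2×2/stride-2 average pooling. This realizes the
  "wavelet as pooling" identity: average pooling discards the three detail
  subbands that the wavelet operator retains.

Subband channels are ordered (LL, LH, HL, HH) blocked per input channel, in
input-channel order. The order is a convention; any fixed permutation is
absorbed by the first convolution that consumes the stack. Level *l* of the
pyramid transforms the LL channels of level *l−1*, giving spatial size
input/2^l and 4·C channels at every level.

### Layer graph

The default graph (4 classes, 512×512×3 input) follows a published model
summary exactly. All convolutions are 3×3 with "same" padding; spatial
halving happens only at the four stride-2 convolutions conv_1_2, conv_2_2,
conv_3_2, conv_4_2. Every convolution is followed by batch normalization
and ReLU. The wavelet taps (levels 1–4) feed conv_1, conv_a, conv_b and
conv_c; three concatenations fuse spectral and spatial branches at 128²,
64² and 32² resolution. The head is avgpool(2, stride 1, same) → flatten
(32768) → dense 2048 → BN → ReLU → dropout, twice, then a dense layer with
one unit per class and a softmax.

Reconstructions and readings the summary forces:

* A `norm_4` batch-normalization row (256 channels) is absent from the
  printed table but required both by relu_4's declared input and by the
  printed non-trainable total of 13,440 = 2·ΣC over 17 BN layers.
* Printed batchnorm parameter cells are read as 4·C totals (2·C trainable
  scale/shift plus 2·C non-trainable moving statistics), the only reading
  consistent with the trainable and non-trainable totals simultaneously.
* `wavelet[k]` inputs denote pyramid level k+1, forced by the consumers'
  parameter counts (all imply 12 input channels) and spatial sizes.
* Downsampling is stride-2 convolution — the table has no pooling rows at
  the halving points. The single explicit pooling layer (pool_5_1) is
  average pooling with window 2, stride 1, same padding, which preserves
  its printed (16,16,128) shape.

The closed-form audit (conv: (9·C_in+1)·C_out; dense: (N_in+1)·N_out; BN:
2C + 2C) reproduces every printed cell and the totals 76,289,732 trainable
and 13,440 non-trainable parameters, and is checked against the executable
backend's own count — two independent routes to the same number.

### Execution backend

No deep-learning framework is used: the graph is bound to a numpy backend
written in this package (im2col/col2im convolutions with TensorFlow-style
"same" padding, batch normalization with momentum-0.9 moving statistics and
eps 1e-3, inverted dropout, softmax cross-entropy, Adam). Gradients are
hand-derived and verified against central finite differences in the test
suite. Average pooling under "same" padding averages only the cells inside
the input (padding is excluded from the count). The wavelet taps are
constants of the input, so no gradient flows through them. Weights are
He-normal, seeded; dropout uses an independent stream split from the same
seed, so a seed fully determines a run on a fixed call sequence.

## Pipeline

* **Patching** — sliding 512×512 windows with 50 % overlap (stride =
  side·(1−overlap)), full windows only, anchored at the top-left corner;
  partial border windows are discarded. If an image axis is shorter than the
  window, the whole extent of that axis is taken and the window is rescaled
  to side×side bilinearly (this is how 700×460 sources still produce one
  valid patch).
* **Augmentation** — each patch becomes 8: the four rotations × {identity,
  vertical mirror}, a subgroup of the dihedral group of the square.
  "Vertical mirror" is the flip across the horizontal axis (top row ↔
  bottom row); composed with the four rotations either reading of the term
  generates the same 8-element set, so downstream results do not depend on
  the choice. Labels are inherited from the source image.
* **Normalization** — per-patch, per-channel mean subtraction, applied
  after the geometric transform so every emitted patch has exactly
  zero-mean channels. Per-patch (rather than dataset-wide) means are the
  closest reading of patch-wise normalization; the choice is configurable
  at the call site.
* **Split** — stratified 70/30 at source-image level, before patching, so
  no patch or augmented variant of a held-out image can reach the training
  set; a runtime assertion enforces disjointness.
* **Decision rule** — patch-level softmax outputs; image-level predictions
  average the softmax vectors over an image's patches and take the argmax.
  Both granularities are reported.

## Training defaults

epochs 200, batch size 3, train fraction 0.7, dropout 0.5, orthonormal
wavelet mode — the reference configuration. Optimizer and learning rate are
not pinned by the reference description; the package defaults to Adam at
1e-4 with cross-entropy, overridable in `TrainConfig`. No early stopping;
the parameter state with the best test accuracy is kept. The per-epoch
history records the running optimization accuracy (dropout and batch
statistics active) and, separately, `train_accuracy` — the end-of-epoch
inference-mode accuracy on the training patches, which is the quantity an
accuracy-vs-epoch curve plots and the one quoted as "training accuracy"
in reports.

## Metrics

Accuracy, sensitivity (TP/(TP+FN)) and specificity (TN/(TN+FP)) from
explicit confusion counts; zero denominators raise an undefined-metric
error rather than silently returning 0. The ROC curve enumerates all
distinct score thresholds (ties grouped); AUC is the trapezoidal area,
which equals the Mann–Whitney concordance probability with ties counted ½ —
the test suite checks this identity against an O(n²) pair enumeration.
Multi-class evaluation is one-vs-rest on argmax predictions; macro averages
are unweighted class means and micro averages pool the counts (both are
reported because the reduction convention is not standardized).

## Synthetic fixtures

The generator emulates only the statistical hooks the method exploits —
class-dependent texture frequency (an oriented sinusoid, cycles per 100 px),
nuclear density (Poisson-placed dark Gaussian spots with channel weighting
mimicking hematoxylin absorption), a base stain color, and white noise —
clipped to [0, 1]. Classes in `default_class_specs` are graded jointly in
texture frequency and spot density (2-class: benign/malignant; 4-class:
normal/benign/in_situ/invasive). A 4× texture-frequency gap makes classes
linearly separable on level-1 detail energy alone (>90 % single-threshold
accuracy), so a trained network exceeding that bar is learning real
structure, not noise. All randomness derives from one master seed through
`SeedSequence`, giving byte-identical regeneration.

What passing tests on these fixtures does **not** show: robustness to stain
variability, cell overlap, magnification changes, or any other property of
real histology. The fixtures validate the machinery (shapes, gradients,
pipeline plumbing, separability transfer), not clinical performance.

## Problem sizes

The end-to-end smoke experiment trains the width-0.25 network on 2-class
fixtures, 20 images/class at 256×256, 5 epochs, batch 3 — 28 training
images → 224 augmented patches per epoch — and evaluates on the held-out
30 %. This configuration separates perfectly well before the 200-epoch
reference schedule would, and one run completes in a few minutes on a
single CPU core. Unit tests use 16–64 px inputs with width multipliers of
1/16–1/32; the full-width 512×512 graph is audited symbolically (shapes and
parameter counts) rather than executed.

## Known limitations

* The backend is CPU/numpy; it is meant for correctness and moderate-scale
  experiments, not for GPU-scale training of the full 76 M-parameter model.
* Only the Haar family is implemented; no inverse transform, undecimated
  variants, or other wavelet families.
* No stain normalization or color augmentation; inputs are assumed RGB in
  [0, 1].
* `width_multiplier` rounds fractional channel counts (with a warning), so
  parameter totals at non-reproducing widths are approximate scalings.
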