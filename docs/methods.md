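# Methods

This note documents the models and procedures implemented in
`granulonet`, the choices made where the design was genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## Problem setting

The package implements a convolutional classifier for small medical-image
corpora — breast-ultrasound images (normal / benign / malignant, or the
binary normal / abnormal collapse) and histopathology patches
(IDC-negative / IDC-positive). Such corpora are typically far too small
to train a large CNN from scratch, so the design combines four
data-efficiency devices: granular-computing preprocessing, a
wide-and-deep inception/residual architecture with few parameters,
learnable activation functions, and spatial attention with deep
supervision.

## Granular computing

An input image (resized with cubic interpolation and normalized to
[0, 1]) is cut into non-overlapping g x g tiles ("granules") on a regular
grid, row-major from the top-left corner; trailing rows and columns that
do not fill a whole tile are dropped, so an H x W image yields
floor(H/g) * floor(W/g) granules. The default g = 32 gives the canonical
7 x 7 = 49-granule grid on a 224 x 224 image.

A pluggable backbone maps each tile to a fixed-length feature vector.
Two deterministic backbones ship with the package: per-channel tile
statistics (mean, standard deviation, mean gradient magnitude; d = 3C)
and a frozen random convolutional extractor with weights drawn once from
a fixed seed. Any stronger extractor — e.g. a truncated pretrained CNN —
can be plugged in through the same callable contract; none is bundled,
keeping the package fully offline and its tests deterministic.

Per-granule features are used in two modes:

* **vector** — mean (or max) pooling over granules gives one descriptor
  per image, suitable for a conventional classifier;
* **highlight** (the mode wired into the training pipeline) — each
  granule's L2 feature norm is min-max rescaled over the image to
  [0.2, 1] and multiplies that granule's pixels, producing a
  saliency-weighted image of the original shape. The floor of 0.2 keeps
  low-saliency tissue visible instead of deleting it; when all norms
  coincide the weighting is the identity. Only highlight mode is
  shape-compatible with the CNN input, which is why it is the pipeline
  default.

## Learnable activation functions

Both activations have the form `LAF(x) = a * F(W * x) + b` with `a`, `b`
and `W` trained by backpropagation together with the network weights.
`F` is max(0, .) after convolutional layers and the logistic function in
dense layers. Initialization is (a, b, W) = (1, 0, 1), so training
starts from the classical ReLU/sigmoid and the activations deform only
if the data rewards it. One (a, b, W) triple is learned per feature
channel (a whole-layer shared triple is available); per-channel is the
convention for parametric activations and honours the scalar form of the
defining formulas. The subgradient of the ReLU form at its kink is 0.

## Architecture

The **R-block** is a residual unit
`out = conv2(LAF_relu(BN(conv1(x)))) + shortcut(x)` with same padding;
the shortcut is the identity when channel counts match and a 1 x 1
projection otherwise. Three filter-size variants exist: R3 (3x3, 3x3),
R5 (5x5, 5x5), R35 (3x3, 5x5). With the residual branch zeroed the
block is exactly the identity map.

The **X-module** runs three R-blocks in parallel, each preceded by a
1 x 1 channel reducer, alongside a 3 x 3 stride-1 max-pool + 1 x 1
branch; the four outputs are concatenated on channels. The architecture
variant (R3_R3_R3, R5_R5_R5, R3_R5_R35) selects the R-block kinds used
at every X-module position. The reducers cut the parameter count
substantially at equal output width (about half at the default widths);
the package can build the reducer-free configuration for comparison.

The **downsample module** concatenates a 3 x 3 stride-2 max pool with a
1 x 1-reduced 3 x 3 stride-2 convolution, halving resolution (ceil) and
widening channels. Downsampling happens only in downsample modules and
pooling layers; everything inside R-/X-modules is same-padded.

**Convolutional attention** computes one scalar score per pixel
(k x k convolution, learnable ReLU, then a 1 x 1 convolution) and
normalizes the scores with a softmax *across spatial positions*, so each
map is a probability distribution over the image summing to 1. A
per-pixel softmax of a single scalar would be identically 1, so the
spatial reading is the only non-degenerate one. The input is multiplied
element-wise by `weights * H*W`; the rescale makes the uniform map the
exact identity instead of collapsing activations by a factor H*W.
Defaults k = 3, stride 1 (the stride is configurable; score maps from a
strided conv are nearest-upsampled back to input resolution).

**Dense attention** projects each position's feature vector to a scalar
with a dense layer, softmaxes over positions, and returns the weighted
sum of feature vectors — attentive global pooling of an (H', W', C) map
to a length-C vector.

The **full network** is, in order: convolutional attention on the input;
a 3 x 3 convolution (+BN +learnable ReLU) followed by a 3 x 3 stride-2
max pool; two X-modules; a downsample module feeding auxiliary
classifier 1; three X-modules; a downsample module feeding auxiliary
classifier 2; one X-module; dense attention; dropout; and a learnable
softmax head (dense -> learnable sigmoid -> dense -> softmax). Auxiliary
classifiers are global-average-pool -> learnable softmax head and are
used only during training.

Open points resolved as package design choices:

* *Stem pooling.* The system follows the GoogLeNet template, which pools
  between its stem and its inception stages; a 3 x 3 stride-2 max pool
  is therefore placed after the stem convolution. It quarters the
  computational cost of every X-module stage, in line with the
  architecture's stated goal of reducing computation, without touching
  the module sequence.
* *Head ordering.* Average pooling, dropout and dense attention cannot
  be composed in that literal order: a 2-D attention cannot follow a
  pooled vector. Dense attention performs attentive pooling itself, so
  it is applied to the last X-module's map and its pooled vector feeds
  dropout and the head.
* *Aux tap points.* Auxiliary classifiers tap the features right after
  each downsample module (the GoogLeNet convention, matching the listed
  positions).
* *Channel widths* are nowhere specified; with base width w the stem has
  w channels and the X-module branch width starts at w/2, doubling after
  each downsample. Defaults: w = 64 at 224 x 224; the desk-scale
  profile uses w = 16 at 64 x 64.

## Training and evaluation

The loss is categorical cross-entropy of the main head plus
0.3 x (CE(aux1) + CE(aux2)). Cross-entropy is used because every head
ends in a softmax over classes; the auxiliary weight 0.3 is the
deep-supervision convention. The optimizer is Adam. Full-scale defaults:
learning rate 1e-4, up to 100 epochs, batch size 32, dropout 0.5. Early
stopping monitors validation loss with patience 10 (default) and
restores the best-validation weights; when no validation set is given,
10% of the training side is carved out group-aware and stratified. A
NaN/Inf loss aborts with a diagnostic rather than training on.

Dataset preparation follows the standard small-corpus recipe: classes
are equalized by seeded down-sampling to the minority count; each image
is tripled (original + a random width/height shift of up to 10% of each
dimension with edge-replication padding + a horizontal flip); the
train/test split (80/20) is stratified by class at the original-image
level and group-aware — an original and its augmented copies always land
on the same side, and the test side keeps originals only, so no
augmented view of a test image can leak into training. Edge replication
is used for the shift padding because black borders are atypical of
ultrasound content. Each operation takes one integer seed and all of its
randomness flows from it, making every pipeline stage bit-reproducible.

Evaluation predicts the argmax of the main head (ties resolve to the
lower class index) and accumulates a K x K confusion matrix (rows =
actual). Accuracy is trace/total; per-class precision, recall and F1 use
the 0/0 := 0 convention and are averaged macro (default) or weighted by
support. Accuracy equals support-weighted recall by construction, which
the tests exercise as an algebraic identity.

## Numerical engine

The network runs on a compact NumPy reverse-mode autodiff engine written
for this package: tensors with backward closures, im2col-lowered
convolutions executed as one GEMM per layer, max pooling with -inf
padding (ties receive gradient at every maximal position — a valid
subgradient), batch normalization with running-moment inference, stable
spatial softmax, inverted dropout, and Adam. Data is float32 in NCHW
layout. Column matrices larger than 32 MB are rebuilt during the
backward pass instead of being retained, and each batch's graph is torn
down eagerly after its optimizer step, keeping the peak resident set of
a desk-scale run around 2 GB. Gradients of every primitive are verified
against central differences in the test suite. Checkpoints store all
weights, every LAF triple, batch-norm running moments and the model
configuration; reloading reproduces forward outputs bit-exactly.

## Synthetic data

The generators emulate the statistical structure of the target corpora
without any downloads:

* **ultrasound** — grayscale multiplicative speckle (gamma-distributed
  with shape 4, lightly smoothed, base intensity 0.45), optionally
  containing a darker lesion: a smooth-edged random ellipse ("benign")
  or an irregular-edged region, an ellipse with a low-order harmonic
  radius perturbation ("malignant"). Maximum lesion contrast is 0.55.
* **histopath** — pink-ish RGB patches (native 50 x 50 scale) with dark
  round nucleus-like blobs; the mean blob count is 8 for the negative
  class plus up to 18 extra for the positive class.

A single `separability` knob in [0, 1] scales every class-conditional
difference (lesion contrast, edge irregularity, blob-density gap). At 0
the class-conditional distributions are identical, so any classifier is
at chance; at 1 the classes are cleanly separable. Generation is a pure
function of (spec, seed). The shape constants above are fixed defaults,
not tuning knobs.

What the phantoms do **not** capture: acoustic shadowing, depth-dependent
gain and anisotropic speckle of real ultrasound; stain variability,
tissue texture and nucleus morphology of real histopathology. Passing
the synthetic benchmarks therefore demonstrates that the pipeline is
wired correctly and can learn a localized low-contrast signal at small
sample size — not that it reaches any particular accuracy on clinical
data.

## Desk-scale benchmark

The standard end-to-end demonstration trains the small profile (64 x 64
input, base width 16, variant R3_R5_R35, ~269k parameters) on a binary
ultrasound phantom task with 200 training and 60 test images. The
training profile uses learning rate 1e-3, at most 12 epochs, batch 32
and early-stop patience 4: with two orders of magnitude fewer gradient
steps than a full-scale run, fewer, larger steps are appropriate, and
the task is learned within a few epochs. At separability 1.0 test
accuracy reaches or exceeds 0.90 in the large majority of seeds
(typically 1.0); at separability 0.0 it stays in the chance band. These
problem sizes are the package's chosen desk-scale conditions; the
full-scale profile (224 x 224, base width 64, lr 1e-4, 100 epochs)
mirrors the original training recipe and is available through the same
configuration objects.

## Known limitations

* CPU-only and single-threaded; full-scale 224 x 224 training is
  possible but slow, and the engine is not intended to compete with a
  GPU framework.
* Only tiling granulation is implemented (no segmentation/superpixel
  granules); no LBP/HOG backbones ship, though the extractor API accepts
  them.
* No DICOM input, no elastic or intensity augmentation, no
  cross-validation, no hyperparameter search.
* The binary "normal/abnormal" collapse of the three ultrasound classes
  is supported via configuration; no specific mapping is hard-coded.
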