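# Methods

This note documents the models implemented in `tflos`, the synthetic data
used to exercise them, and the numerical and design choices that are not
visible from the API alone.

## Scope and intent

The package implements a complete tea-flower phenotyping stack at desk
scale: a single-stage anchor-based detector for three flower classes
(bud, blooming flower, withered flower) with direct per-image counting
output, the detection/counting metric suite, and a small feed-forward
classifier that maps (counts, date) to one of five flowering stages
(IFS, EFS, MFS, LFS, TFS).  No field imagery ships with the package;
seeded synthetic scene and season generators stand in for it, so every
result below is reproducible from a seed on one CPU.  Scores obtained on
synthetic scenes say nothing quantitative about field imagery; what the
test suite establishes is that the implementation is internally correct
(oracle equivalence, reduction properties, metric identities) and that the
training stack can actually learn (scaled-down learning checks).

## The neural-network substrate

No deep-learning framework is used: the layers run on a small tape-based
reverse-mode autodiff engine (`tflos.nn`) over numpy.  Convolution is
im2col + GEMM with an explicit col2im backward; batch normalization is a
fused primitive with the standard closed-form backward; bilinear sampling
scatter-adds its four neighbour weights in the backward pass.  Gradients
of every primitive are tested against central finite differences.  The
engine computes in float32 and preserves float64 end to end when inputs
are float64 (the gradient-check path).

## Detector

Architecture: CSPDarknet-style backbone (stem stride-2 conv, four
Conv/C3 stages, SPPF), PANet top-down/bottom-up neck, three 1x1-conv
heads at strides 8/16/32 predicting 3 anchors x (4 box offsets +
objectness + 3 class logits).  At the default 640-px input the head grids
are 80/40/20.  Three enhancements are config-switchable:

* **SE** after the deepest backbone stride-2 conv (layer 7): global
  average pool per channel, bottleneck `C -> C/16 -> C`, sigmoid gate.
* **ARConv** replacing the 3x3 convs inside chosen backbone C3
  bottlenecks (default stages 2-3).  Two subnets (3x3 conv - BN - SiLU -
  1x1 conv) predict per-pixel kernel height/width maps
  `h = a*sigmoid(f(x)) + b` with `a = 6, b = 1` on both axes, so extents
  live in (1, 7) pixels — bounds chosen to keep sampling local; nothing
  larger is useful at these resolutions.
  Kernel sizes come from the spatial means via `phi(floor(mean))` with
  `phi(x) = x - [x even]`, clamped to >= 1; per-pixel spacing is
  `Z0 = (h0/k_h, w0/k_w)` applied to the integer grid; samples are
  gathered bilinearly with zero padding (so the forced-standard-grid
  configuration reduces exactly to ordinary convolution, which the tests
  exploit); the gathered map is convolved with a single learned kernel
  bank SK (sliced to the active size) and modulated elementwise by two
  1x1-conv affine subnets M and B initialized to the identity (M=1, B=0).
  Gradients flow to the input, SK and the affine subnets; the h/w fields
  steer the grid through a stop-gradient — the sampling geometry is
  treated as data.  A learned-position variant would need gradients of
  bilinear weights with respect to position; it is out of scope and
  nothing in the contracts requires it.
* **CAAFT** after SPPF, before the neck.  Coordinate Attention pools the
  map into per-direction descriptors (1/W row means and 1/H column
  means), encodes them through a shared 1x1 bottleneck, and reweights the
  map by the outer product of the two sigmoid attention profiles.  The
  reweighted map, flattened to a sequence of length H*W, passes through a
  positional-bias-free Attention Free Transformer
  `Y = sigmoid(Q') ⊙ Σ_T softmax_T(K') ⊙ V'` — elementwise gates and a
  single pooled context vector, O(T·d) memory, no T×T matrix — and
  re-enters through a residual connection (the identity pathway; with the
  output gate closed the block is exactly the CA output).  The
  non-linearities are a choice: the gate language of the mechanism implies
  a bounded output gate (sigmoid) and a normalized forget gate (softmax
  over the sequence); the sum pool makes the gate pair convex.

Assignment and loss: a ground truth is assigned to every anchor within a
factor-4 w/h ratio, in its centre cell and the two nearest neighbour
cells.  Loss = 0.05*box + 1.0*obj + 0.5*cls with CIoU box loss, BCE
objectness against the matched IoU (clamped at 0; a constant-1 target is
available as `obj_target="one"` for very short schedules, at the price of
mis-calibrated confidences and therefore poor counting), BCE class loss,
per-scale objectness balance (4, 1, 0.4), and prior-aware head-bias
initialization.  Anchors default to the standard 640-px COCO nine; k-means
re-estimation from the training labels (`anchor_mode="kmeans"`) is what
any small-object dataset should use and is on in all desk-scale recipes.

Inference: heads decode with the sigmoid xy/wh parameterization,
per-box confidence is Pr(object)·Pr(class) of the argmax class (the IoU
factor of the confidence definition is supplied at training time through
the IoU objectness target), greedy per-class NMS at IoU 0.45, confidence
0.25 for counting and 0.001 for mAP sweeps.  Counting is the class-wise
cardinality of the post-NMS detections, written as CSV
(`image,bud,b_flower,w_flower,total`).

Training defaults mirror a full-scale recipe (300 epochs, batch 8, lr
0.01, SGD); the desk-scale recipe used by the learning checks is 40
epochs, batch 2, Adam at lr 3e-3 with cosine decay and EMA weight
averaging (decay 0.997), chosen because from-scratch training in a few
thousand gradient steps needs an adaptive optimizer and a small batch
maximizes steps per epoch under a fixed epoch budget (SGD at the
full-scale learning rate diverges at this scale).  Training is
bit-deterministic under a seed.

**Counting operating point.**  A detector whose mAP is computed by
sweeping all confidences still needs one fixed threshold to count with.
Early in training, small objects yield near-duplicate boxes whose
pairwise IoU sits below the NMS threshold (adjacent-cell predictions on a
sub-stride object), so any fixed default threshold systematically
over-counts until confidences are calibrated.  The package therefore
exposes `calibrate_count_threshold`, which applies quantile
(count-matching) calibration on the *training* split: the threshold is
the confidence of the N-th highest detection where N is the split's true
total object count, i.e. the point at which total predicted count equals
total true count.  This estimator is much lower-variance than a grid
search over per-image squared errors.  The reported counting R² on
validation/test data uses that calibrated operating point; the
general-purpose default threshold remains 0.25.  Random horizontal
flipping (probability 0.5) is always part of the desk-scale training
recipe, and counting evaluation uses horizontal-flip test-time
augmentation (`detect_image(..., tta=True)`): the mirrored pass is an
inference-time two-member ensemble whose merged boxes are sharper, which
directly reduces the duplicate survival that drives counting error.

## Synthetic scenes

`SceneSpec`/`generate_scene` render a layered green canopy (gradient +
translucent leaf ellipses + dark branch strokes) and three object types:
buds as pale filled ellipses (8-20 px long axis), blooming flowers as
white petal rosettes with a yellow core (15-40 px), withered flowers as
irregular brown blob unions (10-30 px).  Class prevalence defaults to
57/25/18 (bud/blooming/withered), the imbalance of a real flowering
season.  A fraction of objects (occlusion_rate) is over-painted by leaf or
branch primitives after all flowers are drawn; an object's visible
fraction is measured on its own mask and objects below
`min_visible_fraction` (default 0.25) are omitted from the labels while
the manifest keeps the true pre-occlusion counts.  Backlight multiplies
brightness by 0.6 and compresses contrast by 0.75 toward the mean;
light-spot artifacts are 1-3 half-opacity white ellipses.  Boxes are the
bounding boxes of the full (pre-occlusion) masks, matching the practice of
labeling partially occluded flowers.  Placement rejects candidates
overlapping an existing object above IoU 0.35, with a bounded retry budget
(`PlacementError` beyond it).

What the generator does **not** emulate: photorealistic texture,
intermediate bud/bloom morphologies, background flowers from neighbouring
plants, perspective and scale variation within a scene.  A detector score
on these scenes is an upper bound of sorts — the shapes are cleaner than
field imagery — so the scaled-down learning check is a capability check of
the training stack, not a performance claim.

## Synthetic seasons

Three lagged Gaussian-shaped curves generate daily expected counts: the
blooming curve peaks at `peak_day` with amplitude `peak_amplitude` and
width `season_length/6`; the bud curve leads by `bud_lead` days at 2.28x
amplitude and the withered curve lags by `wither_lag` days at 0.72x
(ratios from the 57/25/18 prevalence).  Counts are negative binomial with
variance `mu + d*mu^2` (dispersion `d = noise_dispersion`); `d = 0` is
exactly noiseless (`round(mu)`), which the exact tests rely on.  Stage
labels follow the cumulative noiseless blooming curve with fixed
boundaries 10/40/60/90% of the season total for IFS/EFS/MFS/LFS/TFS —
the boundaries are package constants, chosen once to make labels
reproducible, not estimates of any survey rule.

## Stage classifier (TFSC)

Seven layers: 4 input features (bud, blooming, withered counts and
day-of-year/366), six hidden ReLU layers (64, 64, 32, 32, 16, 16), 5-way
softmax.  Day-of-year encoding keeps the feature portable across years,
which matters because the test split is a different year than the
train/val split.  Inputs are z-scored with statistics fitted on the
training split only.  Preprocessing mirrors a two-year survey: accessions
with median total count below 3 are dropped (the "insufficient flowers"
rule made concrete), same-accession-same-date records are averaged in
groups of three in input order (leftovers of 1-2 dropped to keep the rule
exact), year-1 samples split 8:2 train/val, year-2 samples form the test
set.  Training: cross-entropy, Adam, lr 1e-3, batch 16, 80 epochs,
deterministic under seed.  At inference the pipeline averages same-date
records when three or more exist and uses raw counts otherwise (flagged
in the output).

On synthetic seasons with moderate noise the classifier recovers stages
well above 0.8 test accuracy with errors almost exclusively between
adjacent stages — the qualitative signature expected of any ordinal
phenology classifier, since neighbouring stages share boundary samples.

## Metrics

Greedy confidence-ordered one-to-one matching per image and class (ties
by higher IoU, then input order) defines TP/FP/FN; precision, recall and
F1 follow the standard confusion-matrix formulas with explicit
zero-denominator conventions (no detections -> precision 0; classes
without ground truths are skipped from mAP).  AP integrates the precision
envelope over recall exactly (all-point); a 101-point interpolated variant
sits behind a flag.  mAP50-95 averages thresholds 0.50:0.05:0.95 (10
values, the usual convention).  Counting agreement uses
R² = 1 − SS_res/SS_tot on total counts per image (per-class R² available).
Greedy matching can in principle fall below the optimal bipartite
matching; the tests compare it against an exhaustive matcher on small
instances and the committed behaviour is greedy.

## Pipeline

`tflos run` / `run_pipeline` chains synth → train → evaluate → seasons →
TFSC → dynamics with per-stage `.done` markers keyed by a config hash
(re-runs skip completed stages bit-identically) and a manifest recording
config, seed and library versions.  A single global seed fans out to
per-stage seeds through SHA-256 of `"{seed}:{stage}"`, so stages are
independently reproducible.

## Problem sizes in the checks

The oracle suites run on ~100 random small instances per operation.  The
learning checks use: 200 scenes at 160 px for the detector (width
multiple 0.125 — 8 to 128 channels — about 0.09 M parameters), 40 epochs;
and 30 accessions x 2 seasons (~1 440 averaged samples) for the stage
classifier, 80 epochs.  These sizes were chosen so the whole suite runs
on one CPU in well under half an hour while still exercising every
component end to end.

## Known limitations

* Synthetic scenes are far easier than field imagery; absolute detection
  scores do not transfer.
* The ARConv kernel bank is a single resized bank, not a size-conditioned
  selection; both readings satisfy the forward contract and the simpler
  one is implemented.
* Counting calibration at short training schedules is the weakest link:
  small objects produce near-duplicate boxes below the NMS threshold
  until localization sharpens, so counting R² trails mAP substantially
  early in training.
* The stage classifier is trained and validated on synthetic seasons
  only; regional/climatic transfer is untested by construction.
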