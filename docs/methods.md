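# Methods

## Problem and scope

The package estimates a continuous depression-severity score (BDI-II, 0–63)
from short single-subject face videos. Clinical video corpora with BDI-II
labels are access-restricted, so the package is validated entirely on
procedurally generated synthetic data whose severity signal is known by
construction. The goal of the synthetic validation is *mechanistic*: every
operation is checked against closed forms or independent oracles, and the
end-to-end claim is that the pipeline can recover a facial severity signal
when one exists — not that synthetic results transfer to clinical
populations.

## Synthetic data generator

Each frame renders one schematic face (ellipse head, two eyes, nose, mouth
arc) on a smooth textured background, plus i.i.d. Gaussian pixel noise.
Severity s ∈ [0, 63] drives two geometry cues associated with depressed
affect in the clinical literature (reduced smiling, reduced ocular
activity):

| map | form | range |
|---|---|---|
| mouth curvature | `0.35 − 0.70·s/63` | +0.35 (smile) → −0.35 (frown) |
| eye openness | `1.0 − 0.75·s/63` | 1.0 → 0.25 (aperture fraction) |

Both maps are affine and strictly monotone, so monotonicity and
learnability are exactly testable. Defaults: 64×64 frames, face scale
0.62·min(H, W), frame-to-frame centre jitter ≤ 1 px (uniform), noise σ =
0.02 in [0, 1] intensity units — small head motion and sensor noise at a
level where the geometry cues remain dominant, which is what a cooperative
interview recording looks like. Ground truth (tight face box, five
landmarks: eye centres, nose tip, mouth corners) is emitted exactly from
the rendering geometry. Every generator is a pure function of its arguments
including the seed.

What the generator deliberately does **not** model: identity variation,
pose/rotation, illumination changes, occlusion, temporal expression
dynamics, multiple faces. Passing tests therefore demonstrate correctness
of the machinery and recoverability of a geometric severity code, nothing
about real faces.

Detection patches are sampled from rendered 96×96 scenes: face windows with
IoU ≥ 0.65 against the true box (carrying normalised box offsets and
landmarks), part-face windows with IoU ∈ [0.3, 0.65) (offsets only), and
background windows with IoU < 0.3 (half of them from face-free scenes).
Offsets are normalised by the window side; landmarks by window units.

## Detection cascade

Three stages with the canonical proposal→refine→output plan (12, 24, 48 px
inputs; 2/4/10-way heads). All feature convolutions are 3×3 stride 1 and
all pooling 2×2 stride 2; prediction heads are 1×1 convolutions (proposal
stage) or fully connected layers — the kernel-size rule is read as applying
to feature extraction, since a 3×3 head cannot operate on a 1×1 map.
Face probability is the two-logit softmax, equivalently the sigmoid of the
logit gap. Stages are trained independently on patch sets rendered at their
input size with the weighted objective Σ α_j β_ij L_ij; task weights
default to (1, 0.5, 0.5) for the first two stages and (1, 0.5, 1) for the
output stage, which regresses the landmarks.

Inference: pyramid scales `(12/min_face)·0.709^i` down to a 12-px short
side; per-level NMS at 0.5 then global NMS; windows squared, refined, and
re-scored at 24 and 48 px. Score thresholds (0.6, 0.7, 0.7) and NMS
thresholds (0.7, 0.7, 0.7) are configuration-exposed defaults, not fitted
values. Landmarks are mapped through the pre-regression window, the usual
cascade convention. Ties in NMS break toward the lower original index so
results are deterministic. Faces are cropped without rotation alignment
(landmarks are used for cropping only); the crop squares the box, expands
it 15 % per side, clamps to the image and resizes with the same
nearest-neighbour transform used everywhere else.

## Backbone, pyramid fusion, splice

The trunk follows the standard bottleneck residual design (stem 7×7/2 +
pool; stages [3,4,6,3] or [3,4,23,3]; expansion 4; batch norm ε = 1e-5,
momentum 0.1). Input must be divisible by 32. The fusion layer projects
c2..c5 with 1×1 convolutions to a common width (256 by default), adds
2×-upsampled coarser levels top-down, smooths p5 with 1×1 and p2..p4 with
3×3 (zero padding preserves size), then resizes p3..p5 to p2's resolution
by repeated 2× replication and concatenates along channels ("splice"). A
summation mode is available (`splice_mode="sum"`), but concatenation is the
default because it preserves level-specific information. No p1 is built:
fusion consumes c2..c5 only, and the fused features are backbone features
(not raw image downsamples) — where the architecture description is
ambiguous between the two readings, the backbone-features reading is used
as the one consistent with the depicted stage widths.

The nearest-neighbour coordinate transform floors the real-valued source
coordinate and clamps the index into range. Destination coordinates outside
[0, dstW)×[0, dstH) are rejected rather than clamped; with in-range inputs
the clamp is purely defensive (exact arithmetic never needs it).

## Attention

The CCA gate is gap → S = σ(W₂ δ(W₁ z)) → ω = σ(C1D₅(S)) → per-channel
rescale. Two deliberate readings of the published arithmetic:

* **W₂ shape.** The bottleneck expansion is implemented as C × C/r (the
  printed C/r × C would make S the wrong length for the later steps);
  dimensional consistency forces this.
* **Double sigmoid.** Both sigmoids (after the bottleneck and after the 1-D
  convolution) are applied exactly as written, so channel weights lie in
  (0, 1) twice-squashed and the unit strictly attenuates. No simplified
  single-sigmoid mode is provided.

The 1-D convolution uses zero padding (k−1)/2 and an optional bias
(enabled by default, disable with `conv_bias=False`). The fully connected
gate carries no biases, matching the printed form. r = 16 and k = 5 by
default. SE (gap → bottleneck gate → rescale), ECA (gap → 1-D conv →
sigmoid → rescale; structurally CCA minus the bottleneck gate), and CBAM
(channel gate from average+max pooling through a shared MLP, then a 7×7
spatial gate) share the interface for ablation.

Placement: one attention unit on the spliced pyramid output (default). A
`per_block` mode attaching one unit per backbone stage output is provided
for completeness, since the architecture family is drawn both ways; the
post-fusion reading matches the ablation naming ("pyramid + attention
variant") and is the default.

## Training and evaluation layer

Frames inherit their video's label (the corpus being emulated labels whole
clips; no per-frame protocol exists). Split is at the video level, 3:1,
seeded, to prevent leakage between train and validation frames of the same
video; a frame-level split mode exists behind a flag for comparison only.
Optimisation is Adam, lr 0.001, classic L2 weight decay 0.0001, batch 128,
MSE on the raw 0–63 scale (no target normalisation). "Best model" means
minimum validation MSE across epochs; the checkpoint stores parameters,
per-channel input standardisation constants computed on the training split,
and the architecture header. Video-level prediction is the arithmetic mean
of frame scores (median by configuration), clamped to [0, 63] for
reporting. RMSE/MAE are computed over videos; per-subject grouping would
require a subject table and is left to the caller's label table design.

## Numerical engine

`ccanet.nn` is a ~500-line reverse-mode autodiff over numpy: conv2d via
strided windows with an analytic backward, fused batch norm (standard
closed-form gradient), 2×2 max pooling with argmax routing, nearest 2×
upsampling, reductions, concat/slice. Gradients are verified against
central finite differences in float64; conv forward against scipy's
correlate. Determinism: all randomness flows through
`numpy.random.Generator` objects seeded from explicit arguments; a global
CLI seed fans out per stage as `(seed·1000003 + crc32(stage)) mod 2³¹`.

## Problem sizes used in the checks

The shipped checks use a width-reduced depth-50 trunk (stem 8, inner widths
4/8/16/32, 16 pyramid channels) on 64×64 frames, 100 videos × 8 frames,
8 epochs — sizes chosen so the full property suite runs on a single CPU
while leaving the learning margin wide (validation RMSE ≈ 8–10 vs label
standard deviation ≈ 17). The cascade check trains on 2 250 patches per
stage for 12 epochs and evaluates 100 held-out 96×96 frames. The
full-width depth-50/101 plans are exercised for construction and parameter
counts; training them is a GPU-scale undertaking outside the package's
validation scope.

## Known limitations

* The cascade is trained only on synthetic patches; no pretrained face
  detector weights are shipped.
* Batch-norm statistics make training-mode outputs batch-dependent;
  evaluation always uses running statistics.
* The synthetic severity code is purely geometric and noise-free in
  expectation; real depressive affect is temporal, idiosyncratic and far
  weaker — reported synthetic RMSEs are not comparable to clinical ones.
* Video decoding is out of scope: frames-on-disk (PNG directories) is the
  canonical input.
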