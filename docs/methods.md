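# Methods

## Problem and model

The package segments colorectal polyps (foreground) from mucosa
(background) in RGB colonoscopy frames. The model is a U-Net-shaped
encoder–decoder: a HarDNet68 encoder, a DenseASPP multi-scale bridge on
the deepest (stride-32) feature map, and a decoder of three
spatial–channel-attention (SCA) stages consuming encoder skips at
strides 16, 8 and 4, ending in a 1×1 conv + sigmoid head upsampled to
the input size. Output is a per-pixel polyp probability; masks are
obtained by thresholding at 0.5.

### Harmonic dense blocks

Within a block, layer *l* (1-indexed; index 0 is the block input) takes
the concatenation of the outputs of layers *l* − 2ⁿ for every *n* ≥ 0
with 2ⁿ | *l* and *l* − 2ⁿ ≥ 0. Layer widths are
round_even(*k*·*m*^v₂(*l*)) where v₂ is the 2-adic valuation, *k* the
growth rate and *m* = 1.7 the multiplier; round_even(x) = 2·int((x+1)/2)
(nearest even, half up — this reproduces the published HarDNet68
channel plan exactly). The block output concatenates the final and all
odd-indexed layers and is compressed by a 1×1 transition to *t*
channels. Every conv is Conv→BatchNorm→ReLU (convs bias-free under BN).
The stem is a stride-2 3×3 conv to 32, a 3×3 conv to 64, and a 2×2
max-pool; stages 2, 4 and 5 max-pool on entry, so the two middle blocks
share stride 8 and the pyramid taps (after the transition of stages
1, 3, 4, 5) carry 128/320/640/1024 channels at strides 4/8/16/32. The
stride-8 skip is taken after the *second* stride-8 block (t = 320),
which is the variant consistent with the overall parameter budget.

### Bridge and decoder widths

The architecture's printed parameter total (≈23.1M) pins the widths
that the textual description leaves open. We use: DenseASPP branches
with a 1×1 bottleneck to 128 followed by the dilated 3×3 to 256
(= C/4 of the 1024-channel input), dense concatenation, and a final 1×1
projection to 512; decoder widths then halve, 512 → 256 → 128 → 64.
With these choices the canonical network totals 22,942,054 trainable
parameters (−0.7% of the printed budget); projecting the bridge to the
full 1024 channels instead would overshoot it by several millions.

Decoder "dot-product" fusion is elementwise multiplication of the ×2
bilinearly upsampled features with the 1×1-channel-matched skip:
a true inner product would collapse spatial structure. Upsampling is
bilinear with half-pixel centres (align_corners = false). Only the
final output is supervised.

### SCA module

Spatial attention pools across channels per pixel (max and mean),
applies a 1×1 conv to the 2-channel stack and a sigmoid, giving
M_s ∈ (0,1)^{1×H×W}. Channel attention pools across space (global max
and average), passes both vectors through one shared three-layer
bottleneck C → C/8 → C/8 → C (three layers as specified, not the more
common two), concatenates and maps 2C → C with a 1×1 transform and a
sigmoid, giving M_c ∈ (0,1)^{C×1×1}. The two attended tensors are
concatenated (2C) and fused back to C by a 1×1 conv–BN–ReLU — the
fusion operator is our choice, needed to keep decoder widths defined.
For channel counts not divisible by 8 the bottleneck width is
ceil(C/8), so small test tensors remain valid.

## Loss

L_total = w_d·L_dice + w_f·L_focal with default weights (1, 1).
Dice loss is computed per image and averaged over the batch, with
smoothing constant s (default 1.0) in numerator and denominator; with
s = 0 an empty-prediction/empty-target image is defined as loss 0.
Focal loss uses the two-sided balanced form: p_t = p on polyp pixels
and 1 − p on background, α_t = α and 1 − α respectively (defaults
α = 0.25, γ = 2, the standard focal-loss values; the task description
names α and γ but does not fix them). Probabilities are clamped to
[1e-7, 1 − 1e-7] before the log. With γ = 0 the loss reduces to the
α-balanced cross entropy (at α = 0.5, exactly half the plain BCE), the
reduction the tests verify against a brute-force oracle.

## Metrics

mDice, mIoU, sensitivity TP/(TP+FN) and specificity TN/(TN+FP) are
computed from per-image confusion counts on masks binarized at 0.5 and
averaged over images. (The printed sensitivity formula in the source
material duplicates the IoU expression; the prose definition TP/(TP+FN)
is used.) Degenerate conventions: with an empty ground truth and empty
prediction, dice/iou/sens are 1 (0 if the prediction is non-empty);
specificity is 1 when there is no background. The structure measure
S = α·S_O + (1−α)·S_R, α = 0.5, follows the reference definition:
S_O compares foreground/background mean–dispersion statistics of the
raw probability map against the ground-truth regions; S_R splits the
image into four quadrants at the ground-truth centroid and aggregates
SSIM-style structural scores weighted by quadrant area; an empty
(all-foreground) ground truth scores 1 − mean(pred) (mean(pred)).
S-measure and MAE consume raw probabilities, not binarized masks.

## Training protocol

Adam (β = 0.9/0.999), learning rate 1e-4, batch size 4, up to 300
epochs, early stopping when validation mDice has not improved for 50
consecutive epochs, returning the best-validation checkpoint.
"Validation accuracy" for early stopping is taken to be mDice, the
headline metric. No LR schedule, no gradient clipping. All randomness
(init, shuffling, splits, augmentation) derives from explicit integer
seeds; training is single-threaded-CPU reproducible.

Data protocol: source images are split 80/10/10 (val/test sizes
rounded, remainder to train) **before** augmentation, at the
source-image level, so augmented variants never leak across splits.
Each training image yields 20 variants: rotation always (angle uniform
in ±30°, bilinear for the image, nearest for the mask), centre crop to
160×160 with probability 0.5 followed by a resize back to the native
size, Gaussian blur of the image only (3×3 kernel; sigma 0.8 via the
standard kernel-size rule, as no sigma is specified) with probability
0.5; augmentation happens at native size and the 256×256 resize comes
last. Masks are binarized at >127 of 255 on load and re-binarized after
every geometric transform.

## Synthetic data

`synth_generate` emulates the *structure* of the public polyp
benchmarks: a low-frequency pink/red mucosa-like background (Gaussian-
filtered noise around a randomized base hue), 1–3 elliptical lesions
per frame with total coverage drawn from 5–40% of the image, rendered
as a low-contrast darkening/reddening with Gaussian-feathered borders
(σ = size/40), plus 2–6 small specular highlight blobs. The mask is the
union of the ellipses *before* feathering. It does not emulate real
endoscopy optics: no vignetting, lens distortion, motion blur, folds,
vascular texture, instruments, or lesion morphology beyond ellipses.
Tests passing on this generator therefore validate the pipeline's
mechanics (shapes, wiring, optimization, metrics) and the model's
ability to learn low-contrast blob segmentation — not clinical
performance on Kvasir-class data, which requires the real datasets and
GPU-scale training and is out of scope here.

## Numerical core and problem sizes

The network runs on a small numpy reverse-mode autodiff engine written
for this package (im2col convolutions over BLAS matmul, dedicated
batch-norm and bilinear-resize kernels, tie-splitting max-pool
gradients, float32 throughout). Weight init is Kaiming-uniform from a
per-model seed.

The test suite exercises two presets of the same architecture family:
the canonical 22.9M-parameter network (built for parameter counting and
shape checks; forwarded at 64×64) and a `TINY_NETWORK` preset
(stem (8, 16), five 2-layer blocks, m = 1.3, ≈176k parameters) for
training smoke runs. The learnability check overfits 8 synthetic 96×96
pairs in ≤200 Adam steps at lr 1e-3 and reaches train mDice ≥ 0.95 in
about half a minute of CPU; these sizes are the package's own choice of
smoke-test scale, large enough to exercise every module end to end.

## Known limitations

* No ImageNet pretraining: the encoder trains from scratch, so
  benchmark-scale accuracy claims are out of reach by design here.
* Single-class (polyp/background) output only; no deep supervision,
  test-time augmentation, or 3D extension.
* BatchNorm statistics with batch size 4 are noisy; eval mode uses
  running averages, and per-sample independence holds only in eval.
* The autodiff engine favours clarity over speed; canonical-scale
  256×256 training is possible but slow on CPU.
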