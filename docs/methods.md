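# Methods

This note records the models, parameter choices and numerical decisions
behind `mrimotion`, and what the reduced-scale experiments do and do not
demonstrate.

## Degradation model

A blurred slice is `I_B = clip(I_S ⊙ K + N, 0, 1)` with `⊙` true 2-D
convolution (kernel flipped; `scipy.ndimage.convolve`).  On the even
16×16 kernel canvas the convolution center is cell `(8, 8)`; a kernel
whose mass sits elsewhere shifts image content, which is deliberate —
kernels are kept in their random positions and the shift is removed
later by registration.  The boundary rule defaults to reflection
(avoids dark frames around the head); zero-padding is available and is
what the direct-sum oracle tests use.  `N` defaults to none: dataset
building uses pure convolution, and optional zero-mean Gaussian noise
is available with configurable σ.

## Blur kernels

Motion trajectories are modeled as constrained random walks on a 16×16
grid: start uniform, each step uniform over admissible moves, where a
move must stay on the grid, be adjacent to the last cell (8-connected
by default; 4-connected available), not revisit a cell, and keep a
minimum Euclidean separation (default 1.5 px) from every previously
visited cell except its immediate predecessor.  The memory depth
defaults to the whole path.  A walk with no admissible move is aborted
and retried, up to 256 attempts per kernel.  Lengths are drawn
uniformly on [1, 15] by default (no distribution is implied by the
motion model; 15 is the point beyond which streaks over-blur a 256 px
slice).  Rasterization puts weight `1/k` on each of the `k` visited
cells — the constant-velocity reading; no sub-pixel anti-aliasing.
`recenter_kernel` translates a walk so its centroid sits at the
convolution center, for uses that need shift-free blurring without a
registration stage.

The 8-connected/1.5 px defaults are configuration, not claims: the
validity suite and the brute-force enumeration oracle in the tests pin
the semantics for any configured values.

## Radial-stretch augmentation

`IMG_new(P) = IMG_old(C + u(1+ε)(P−C))` with `u = |P−C|/R` inside the
circle `(C, R)`; outside pixels are untouched.  ε defaults to 0.2.
Note the formula's boundary behavior: a pixel at `u = 1` samples from
radius `(1+ε)R`, *outside* the circle, so a residual intensity jump of
order `ε·R·|∇I|` can remain at the rim.  The formula is applied
verbatim and the jump documented rather than silently repaired.  Source
points are sampled bilinearly (the minimal smooth choice) with edge
clamping when `(1+ε)R` exits the image near borders.  Sampling
defaults: center uniform with a 16 px margin, radius uniform on
[16, 64] px, four variants per slice (matching a ≈4× expansion of a
sharp-slice library).  At ε = 0 the map is *not* the identity — it
magnifies the central region and fixes only the rim; the tests encode
this analytically.

## Registration of training pairs

The blurred image is warped onto the sharp frame (the sharp image is
the fixed target) and then histogram-matched to it.  Landmarks are ORB
keypoints with binary descriptors, matched exhaustively with Hamming
distance and cross-checking.  A convolution shift is a pure
translation, so the default transform family is translation; the fit
enumerates every match as a candidate shift, scores candidates by
inlier count within 1.0 px (ties by mean inlier residual), and refines
with the inlier mean — deterministic with no sampling.  A similarity
fit (seeded RANSAC) is kept for robustness experiments.  Alignment
failure (e.g. featureless images) falls back to the identity transform
and flags the pair rather than raising.

## Quality metrics

Intensities are unit-range throughout, so RMSE is on [0, 1] and
`PSNR = −20·log10(RMSE)`; an RMSE of 0.163 corresponds to 15.76 dB,
which is the regime the degradation-level tables live in — this is why
the unit-range convention is the default, with the [0, 255] scale
available via the `scale`/`peak` arguments.  Identical pairs (infinite
PSNR) are capped at a 99 dB sentinel in tabular output.  Degradation
levels bin by the degraded image's PSNR into `<17`, `[17,18)`,
`[18,19)`, `[19,20)`, `>20` (half-open; 20 dB falls in the top bin).
Reduction% is the per-image mean of `(m_deg − m_corr)/m_deg·100`
(mean-of-ratios) by default; ratio-of-means is a config switch.  Gain
is the mean per-image PSNR difference.

Before any metric, model outputs are histogram-matched to the
*original* image: the sharp target in paired evaluation, the degraded
input in unpaired (real-scan) evaluation where no ground truth exists.
Anchoring paired evaluation on the blurred input instead would force
the restored image's histogram back to the blurred one and measurably
cancel restoration gains.

PIQE is implemented from its published block-wise MSCN algorithm
(16×16 blocks, activity threshold 0.1 on MSCN variance, 6-pixel edge
segments flagged below 0.1 standard deviation, center/surround noise
criterion, pooling constant C = 1, score `100·(Σ + C)/(C + N_active)`
clipped to [0, 100]).  A uniform field has no active blocks and scores
exactly 100.  On piecewise-constant synthetic phantoms the blockiness
criterion fires on structure edges, so clean phantoms score high in
absolute terms; the scorer is still strictly monotone under increasing
blur and under added noise on textured bases, which is what the
evaluation relies on.  Scores are pinned by closed-form anchors,
property tests, and a frozen 20-image regression suite.

## Restoration model

Generator: encode block 1 is a 7×7 stride-1 convolution (batch norm,
ReLU); encode blocks 2–5 are 3×3 stride-2 (filters b, 2b, 4b, 4b, 4b
with b = 64); 16 residual blocks (two 3×3 conv–BN–ReLU each, additive
skip) at the bottleneck; four 3×3 stride-2 transposed-conv blocks
mirror the four downsamplings; a 7×7 head with tanh produces a residual
that is *added to the input*.  Five encode but four decode blocks means
exactly four downsamplings are invertible, hence the stride-1 first
block.  Batch normalization is used uniformly wherever a normalization
layer is called for.  The head convolution is zero-initialized, so an
untrained model is exactly the identity — training starts from "do no
harm" and the first gradients flow into the head before deeper layers.
Input sides must be multiples of the total stride (16 at defaults).

Discriminator: seven 4×4 convolutional blocks, filters doubling from
64 and capped at 512, strides 2 for the first five blocks then 1, each
with batch norm and ReLU; a final 4×4 convolution to one channel,
global average pooling and a sigmoid give one probability per image,
thresholded at 0.5.

Loss: `L = L_GAN + λ·L_X + β·L_MSE`, λ = 100, β = 50.  `L_GAN` is the
vanilla log-loss value `E[log D(x)] + E[log(1 − D(G(z)))]` with
probabilities clamped to `[1e-7, 1 − 1e-7]`; the discriminator
maximizes it and the generator minimizes the second term.  `L_X` is the
mean squared distance between feature maps of the generated and target
images under a frozen, seed-initialized convolutional stack — the
perceptual space only needs to be a fixed nonlinear map, and a
deterministic random stack keeps the package download-free; an adapter
for pretrained features can be dropped in behind the same interface.
`L_MSE` is pixel-wise mean squared error.  The content terms are
evaluated on the 8-bit [0, 255] intensity scale
(`LossSpec.intensity_scale`): with λ = 100 and β = 50 this puts the
content terms orders of magnitude above the adversarial term, which is
the regime in which the composite objective actually converges —
measured on unit-range intensities the adversarial input-gradient is
~25× the β-weighted MSE gradient and pixel fidelity degrades.
`total_loss()` itself is a pure function of whatever arrays it is
given.

Training alternates one discriminator step (real batch, then generated
batch) with one generator step, Adam at learning rate 1e-4, batch 16,
250 epochs, 4:1 train/validation split at the full protocol.  The
history records per-step discriminator loss, adversarial value,
perceptual and pixel losses, the composite generator objective, and
validation MSE at epoch boundaries.  Non-finite losses abort with the
step named.  Everything is seeded; two runs with one seed on one
machine produce identical histories.

## Reduced-scale protocol

Full-protocol training is a multi-day GPU job, so the package defines a
reduced-scale reference protocol (`mrimotion.protocols`) used by the
tests and the results-reproduction script:

- 21 distinct phantoms (7 per plane) at 64×64 — distinct sources
  because with few sources the model memorizes them and held-out
  performance collapses;
- kernels of length 7–15 translated to the convolution center, so
  pairs are pixel-registered by construction (at 64 px, ORB alignment
  is unreliable and its errors would contaminate the learning
  measurement; registration is tested separately at native
  resolution);
- a narrow, fully local generator (base 8 filters, one encode block,
  two residual blocks) — at 50 steps only a local deblurring operator
  is learnable, and a large receptive field at tiny scale memorizes;
- batch 4, 50 Adam steps at learning rate 1e-3 (1e-4 moves an
  identity-initialized model too little to measure in 50 steps);
- evaluation on a *fresh* seed's phantoms blurred with length 9–15
  kernels — clearly degraded images, mirroring the low-PSNR
  degradation levels of the full protocol.  An under-trained model is
  a fixed-strength deblurrer: it helps heavily blurred images and can
  hurt nearly clean ones, so the held-out set is the regime where
  correction is meaningful.
- the composite loss decrease is measured on first-10 vs last-10 step
  means (single-batch values are sampling noise).

Under this protocol 50 steps reliably cut the composite objective by
~5–8×, reduce validation MSE, and yield a positive held-out PSNR gain
that exceeds an identity-checkpoint baseline evaluated identically.

## What the phantoms do and do not show

The phantom generator produces deterministic, plane-tagged, landmark-
rich slices with realistic intensity banding, but it is not an
anatomical or MR-physics simulation: no bias fields, no Rician noise,
no k-space artifacts, piecewise-smooth rather than textured tissue.
Passing tests demonstrate that every stage implements its contract and
that the adversarial model genuinely learns blur inversion at reduced
scale; they do not certify performance on clinical scans, which
requires the full-scale protocol on real data (the `io_read_slices`
NIfTI path and the per-plane configs exist for exactly that use).

## Known limitations

- The adversarial term at reduced scale is numerically cosmetic; its
  effect on perceptual quality only manifests at full training scale.
- PIQE absolute values on synthetic piecewise-constant images sit high
  compared with natural images; comparisons (degraded vs corrected,
  more vs less blur) are the meaningful quantities.
- The translation-only transform family cannot absorb rotational
  registration error; the similarity mode exists but is not the
  default.
- Batch-norm running statistics after very few steps differ from batch
  statistics; at the protocol's 50 steps the measured difference is
  negligible (<0.05 dB).
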