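# mrimotion

Simulation and adversarial correction of motion blur in 2-D brain MRI
slices.

In-scanner head motion smears the acquired signal and is a major source
of error when reading structural brain MRI.  Restoring a sharp slice
from a blurred one without knowing the blur is a *blind deconvolution*
problem: the observed image is modeled as

```
I_B = I_S ⊙ K + N
```

where `I_S` is the unknown sharp slice, `K` an unknown convolution
kernel (point-spread function), `N` noise, and `⊙` 2-D convolution.
Head motions on short time scales follow simple curves, so plausible
kernels are short curvilinear paths.  This package implements the full
loop for studying that model:

- **`phantom`** — seeded 256×256 brain-like slice phantoms (skull-like
  rim, tissue structure, ventricle-like cavities, dark background) with
  plane-dependent geometry (sagittal/axial/coronal), so every stage is
  testable offline with no data download.
- **`kernels`** — families of blur kernels from constrained random
  walks on a 16×16 grid: continuous, self-avoiding, never re-approaching
  visited cells, lengths up to 15, 256 attempts per kernel; rasterized
  to normalized convolution matrices.
- **`morph`** — radial-stretch augmentation
  `IMG_new(P) = IMG_old(C + u(1+ε)(P−C))`, `u = |P−C|/R`, ε = 0.2,
  inside a random circle: cheap emulation of inter-subject
  morphological variability.
- **`degrade`** — the forward model: true convolution with a kernel,
  optional additive Gaussian noise, unit-range clipping.
- **`register`** — ORB keypoints + brute-force Hamming matching +
  deterministic inlier-consensus translation fit, then histogram
  matching, to undo the positional shift convolution introduces when
  building (blurred, sharp) training pairs.
- **`metrics` / `piqe`** — full-reference RMSE/PSNR (unit-range
  convention, `PSNR = −20·log10(RMSE)`), degradation-level binning
  (`<17`, `[17,18)`, …, `>20` dB), Reduction%/Gain report tables, and a
  no-reference PIQE scorer built on block-wise MSCN analysis.
- **`model`** — the conditional adversarial restoration network: a
  residual encoder/decoder generator (5 encode blocks, 16 residual
  blocks, 4 transposed-conv decode blocks, 7×7 first kernel, tanh
  residual head), a 7-block 4×4-kernel discriminator (filters 64→512,
  sigmoid probability), and the composite loss
  `L = L_GAN + λ·L_X + β·L_MSE` with λ = 100, β = 50, trained with
  Adam (lr 1e-4, batch 16 at full protocol).  The network stack is a
  small self-contained numpy layer framework with finite-difference-
  verified backward passes.
- **`pipeline` / `cli`** — end-to-end orchestration (phantoms → morphs
  → blur → aligned pairs → train → evaluate) with YAML configuration,
  per-plane dataset splits, provenance manifests, and full
  one-seed determinism.

## Worked example

```python
import mrimotion as mm
from mrimotion.protocols import run_smoke_training, heldout_improvement

# a sharp phantom slice and a curvilinear blur kernel
sharp = mm.make_phantom(seed=7, plane="axial", size=256)
family = mm.generate_family(100, length_min=5, length_max=15, seed=1)
blurred = mm.degrade(sharp, family[0])
print(f"RMSE {mm.rmse(blurred, sharp):.3f}  PSNR {mm.psnr(blurred, sharp):.2f} dB")

# align the blurred slice back onto the sharp frame
pair = mm.align_pair(blurred, sharp)
print(f"shift {pair.transform.shift}  aligned RMSE {mm.rmse(pair.degraded, sharp):.3f}")

# 50 optimizer steps at reduced scale, scored on held-out degraded phantoms
ckpt, history = run_smoke_training(seed=11)
print(heldout_improvement(ckpt, seed=77))
```

prints (exact numbers depend only on the seeds):

```
RMSE 0.133  PSNR 17.51 dB
shift (-3.7819942399999986, 4.02199424)  aligned RMSE 0.031
{'gain_db': 1.8679641852123514, 'rmse_reduction_pct': 19.114670195591607,
 'rmse_degraded': 0.07031039071982272, 'rmse_corrected': 0.05759129124724635, 'n': 21}
```

The blur costs ~0.13 RMSE, about half of which is a positional shift
that registration removes; 50 training steps of the adversarial model
then recover a further ~19% of the remaining error (+1.9 dB) on
phantoms and kernels it never saw.

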