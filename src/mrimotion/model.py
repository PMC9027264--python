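"""Conditional adversarial restoration model for motion-blurred slices.

The generator is a residual encoder/decoder: five convolutional encode
blocks (7x7 kernel first, 3x3 elsewhere; the first block keeps full
resolution, the next four downsample by 2), sixteen residual blocks at
the bottleneck, four transposed-convolution decode blocks mirroring the
four downsamplings, and a tanh head whose output is *added to the input*
(the network learns the residual between blurred and sharp).  The
discriminator is a seven-block 4x4-kernel CNN whose filter count rises
from 64 to 512, pooled to a single sigmoid probability; 0.5 is the
real/fake decision threshold.

Training minimizes  L = L_GAN + lambda * L_X + beta * L_MSE  with
lambda = 100 and beta = 50: the vanilla adversarial log-loss, a
perceptual term (squared distance between feature maps of generated and
target images under a frozen convolutional feature extractor), and
pixel-wise MSE, which is required for stable convergence.  Optimization
is Adam at learning rate 1e-4, alternating one discriminator step with
one generator step.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import nn
from .phantom import SliceImage
from .register import TrainingPair, histogram_match

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "LossSpec",
    "TrainConfig",
    "TrainingFault",
    "Generator",
    "Discriminator",
    "FeatureExtractor",
    "build_generator",
    "build_discriminator",
    "total_loss",
    "train",
    "correct",
    "Checkpoint",
]

_PROB_EPS = 1e-7


class TrainingFault(RuntimeError):
    """A non-finite loss component during training."""


@dataclass
class GeneratorSpec:
    in_channels: int = 1
    base_filters: int = 64
    n_encode_blocks: int = 5
    first_kernel: int = 7
    other_kernel: int = 3
    n_residual_blocks: int = 16
    n_decode_blocks: int = 4
    residual_output: bool = True

    def validate(self) -> None:
        if self.n_encode_blocks != self.n_decode_blocks + 1:
            raise ValueError(
                "n_encode_blocks must equal n_decode_blocks + 1 so every "
                "downsampling has a mirrored upsampling"
            )
        if min(self.base_filters, self.first_kernel, self.other_kernel) < 1:
            raise ValueError("filters and kernel sizes must be positive")

    @property
    def encoder_filters(self) -> tuple[int, ...]:
        b = self.base_filters
        plan = [b, 2 * b] + [4 * b] * (self.n_encode_blocks - 2)
        return tuple(plan[: self.n_encode_blocks])

    @property
    def decoder_filters(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_filters[:-1]))

    @property
    def total_stride(self) -> int:
        return 2 ** (self.n_encode_blocks - 1)


@dataclass
class DiscriminatorSpec:
    in_channels: int = 1
    n_blocks: int = 7
    kernel: int = 4
    base_filters: int = 64
    max_filters: int = 512
    decision_threshold: float = 0.5

    def validate(self) -> None:
        if self.n_blocks < 1 or self.kernel < 1:
            raise ValueError("n_blocks and kernel must be positive")
        if self.base_filters > self.max_filters:
            raise ValueError("base_filters must not exceed max_filters")

    @property
    def filters(self) -> tuple[int, ...]:
        return tuple(min(self.base_filters * 2**i, self.max_filters) for i in range(self.n_blocks))

    @property
    def strides(self) -> tuple[int, ...]:
        return tuple(2 if i < 5 else 1 for i in range(self.n_blocks))


@dataclass
class LossSpec:
    """Composite-loss weights and the intensity scale the loss is computed on.

    With ``intensity_scale`` = 255 the perceptual and pixel terms are
    evaluated on 8-bit-scale intensities, which (together with
    lam = 100, beta = 50) makes the content terms dominate the
    adversarial term numerically — the regime in which the composite
    objective converges; on unit-range intensities the content terms
    would be ~6.5e4 times smaller and the adversarial gradient would
    swamp them.
    """

    lam: float = 100.0
    beta: float = 50.0
    intensity_scale: float = 255.0


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 250
    split: tuple[int, int] = (4, 1)
    seed: int = 0
    max_steps: int | None = None
    loss: LossSpec = field(default_factory=LossSpec)
    plane: str = "xyz"  # tag carried into checkpoints: sagittal/axial/coronal/xyz
    device: str = "cpu"
    checkpoint_every: int | None = None

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if min(self.split) <= 0:
            raise ValueError("split fractions must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class _ResidualBlock(nn.Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator, name: str):
        self.body = nn.Sequential(
            nn.Conv2d(channels, channels, kernel, rng=rng, name=f"{name}.c1"),
            nn.BatchNorm2d(channels, name=f"{name}.bn1"),
            nn.ReLU(),
            nn.Conv2d(channels, channels, kernel, rng=rng, name=f"{name}.c2"),
            nn.BatchNorm2d(channels, name=f"{name}.bn2"),
            nn.ReLU(),
        )

    def params(self):
        return self.body.params()

    def forward(self, x, training=False):
        return x + self.body.forward(x, training=training)

    def backward(self, grad):
        return grad + self.body.backward(grad)


class Generator(nn.Module):
    """Residual restoration network; callable on (N, 1, H, W) batches."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng([seed, 0x6E67])
        enc_f = spec.encoder_filters
        layers: list[nn.Module] = [
            nn.Conv2d(spec.in_channels, enc_f[0], spec.first_kernel, stride=1, rng=rng, name="enc0"),
            nn.BatchNorm2d(enc_f[0], name="enc0.bn"),
            nn.ReLU(),
        ]
        for i in range(1, spec.n_encode_blocks):
            layers += [
                nn.Conv2d(enc_f[i - 1], enc_f[i], spec.other_kernel, stride=2, rng=rng, name=f"enc{i}"),
                nn.BatchNorm2d(enc_f[i], name=f"enc{i}.bn"),
                nn.ReLU(),
            ]
        for i in range(spec.n_residual_blocks):
            layers.append(_ResidualBlock(enc_f[-1], spec.other_kernel, rng, name=f"res{i}"))
        dec_in = enc_f[-1]
        for i, f in enumerate(spec.decoder_filters):
            layers += [
                nn.ConvTranspose2d(dec_in, f, spec.other_kernel, stride=2, pad=1, output_pad=1, rng=rng, name=f"dec{i}"),
                nn.BatchNorm2d(f, name=f"dec{i}.bn"),
                nn.ReLU(),
            ]
            dec_in = f
        # Residual head starts at zero so the untrained model is the identity.
        layers += [
            nn.Conv2d(dec_in, spec.in_channels, spec.first_kernel, stride=1, rng=rng, zero_init=True, name="head"),
            nn.Tanh(),
        ]
        self.body = nn.Sequential(*layers)

    def params(self):
        return self.body.params()

    def _check_size(self, x: np.ndarray) -> None:
        ts = self.spec.total_stride
        for axis, n in (("height", x.shape[2]), ("width", x.shape[3])):
            if n % ts != 0:
                raise ValueError(f"input {axis} {n} is not a multiple of the total stride {ts}")

    def forward(self, x, training=False):
        self._check_size(x)
        residual = self.body.forward(x, training=training)
        return x + residual if self.spec.residual_output else residual

    def backward(self, grad):
        g = self.body.backward(grad)
        return grad + g if self.spec.residual_output else g


class Discriminator(nn.Module):
    """Real-vs-generated classifier emitting one probability per image."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng([seed, 0x6473])
        layers: list[nn.Module] = []
        in_ch = spec.in_channels
        for i, (f, s) in enumerate(zip(spec.filters, spec.strides)):
            layers += [
                nn.Conv2d(in_ch, f, spec.kernel, stride=s, pad=1, rng=rng, name=f"d{i}"),
                nn.BatchNorm2d(f, name=f"d{i}.bn"),
                nn.ReLU(),
            ]
            in_ch = f
        layers += [
            nn.Conv2d(in_ch, 1, spec.kernel, stride=1, pad=1, rng=rng, name="dhead"),
            nn.GlobalAvgPool(),
            nn.Sigmoid(),
        ]
        self.body = nn.Sequential(*layers)

    def params(self):
        return self.body.params()

    def forward(self, x, training=False):
        return self.body.forward(x, training=training)[:, 0]

    def backward(self, grad):
        return self.body.backward(grad[:, None])

    def classify(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False) >= self.spec.decision_threshold


class FeatureExtractor(nn.Module):
    """Frozen, seed-initialized convolutional stack for the perceptual loss.

    The perceptual term compares images in a fixed nonlinear feature
    space; any frozen convolutional map serves, and a deterministic
    seed-initialized stack keeps the package download-free.  Parameters
    are never updated; gradients only flow through to the input.
    """

    def __init__(self, in_channels: int = 1, width: int = 16, seed: int = 0):
        rng = np.random.default_rng([seed, 0xFEA7])
        self.body = nn.Sequential(
            nn.Conv2d(in_channels, width, 3, rng=rng, name="f0"),
            nn.ReLU(),
            nn.Conv2d(width, 2 * width, 3, stride=2, rng=rng, name="f1"),
            nn.ReLU(),
            nn.Conv2d(2 * width, 2 * width, 3, rng=rng, name="f2"),
        )
        for p in self.body.params():
            p.trainable = False

    def params(self):
        return self.body.params()

    def forward(self, x, training=False):
        return self.body.forward(x, training=False)

    def backward(self, grad):
        return self.body.backward(grad)


def build_generator(spec: GeneratorSpec | None = None, seed: int = 0) -> Generator:
    return Generator(spec or GeneratorSpec(), seed=seed)


def build_discriminator(spec: DiscriminatorSpec | None = None, seed: int = 0) -> Discriminator:
    return Discriminator(spec or DiscriminatorSpec(), seed=seed)


class LossComponents(NamedTuple):
    total: float
    l_gan: float
    l_x: float
    l_mse: float


def total_loss(
    generated: np.ndarray,
    target: np.ndarray,
    d_real: np.ndarray,
    d_fake: np.ndarray,
    features: FeatureExtractor | None = None,
    lam: float = 100.0,
    beta: float = 50.0,
) -> LossComponents:
    """Composite objective L = L_GAN + lam*L_X + beta*L_MSE.

    ``L_GAN`` is the adversarial value  E[log D(x)] + E[log(1 - D(G(z)))]
    with probabilities clamped away from {0, 1}; ``L_X`` the mean squared
    feature-map distance; ``L_MSE`` the mean squared pixel error.
    """
    p_real = np.clip(np.asarray(d_real, dtype=np.float64), _PROB_EPS, 1 - _PROB_EPS)
    p_fake = np.clip(np.asarray(d_fake, dtype=np.float64), _PROB_EPS, 1 - _PROB_EPS)
    l_gan = float(np.mean(np.log(p_real)) + np.mean(np.log(1.0 - p_fake)))
    l_mse = float(np.mean((generated - target) ** 2))
    if features is not None:
        fg = features.forward(generated)
        ft = features.forward(target)
        l_x = float(np.mean((fg - ft) ** 2))
    else:
        l_x = 0.0
    total = l_gan + lam * l_x + beta * l_mse
    comps = LossComponents(total=total, l_gan=l_gan, l_x=l_x, l_mse=l_mse)
    if not all(math.isfinite(v) for v in comps):
        raise TrainingFault(f"non-finite loss component: {comps}")
    return comps


@dataclass
class Checkpoint:
    """Serializable snapshot: parameters, buffers, specs, config, plane tag."""

    gen_spec: GeneratorSpec
    params: dict[str, np.ndarray]
    bn_buffers: dict[str, np.ndarray]
    seed: int = 0
    plane: str = "xyz"
    meta: dict = field(default_factory=dict)

    def build(self) -> Generator:
        g = Generator(self.gen_spec, seed=self.seed)
        for p in g.params():
            p.value[...] = self.params[p.name]
        for layer, prefix in _iter_bn(g):
            layer.running_mean = self.bn_buffers[f"{prefix}.rm"].copy()
            layer.running_var = self.bn_buffers[f"{prefix}.rv"].copy()
        return g

    @classmethod
    def from_generator(cls, g: Generator, seed: int, plane: str = "xyz", meta: dict | None = None) -> "Checkpoint":
        params = {p.name: p.value.copy() for p in g.params()}
        buffers = {}
        for layer, prefix in _iter_bn(g):
            buffers[f"{prefix}.rm"] = layer.running_mean.copy()
            buffers[f"{prefix}.rv"] = layer.running_var.copy()
        return cls(gen_spec=g.spec, params=params, bn_buffers=buffers, seed=seed, plane=plane, meta=meta or {})

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"param:{k}": v for k, v in self.params.items()}
        arrays.update({f"buffer:{k}": v for k, v in self.bn_buffers.items()})
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "gen_spec": asdict(self.gen_spec),
            "seed": self.seed,
            "plane": self.plane,
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "Checkpoint":
        path = Path(path)
        side = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))
        params = {k[6:]: data[k] for k in data.files if k.startswith("param:")}
        buffers = {k[7:]: data[k] for k in data.files if k.startswith("buffer:")}
        return cls(
            gen_spec=GeneratorSpec(**side["gen_spec"]),
            params=params,
            bn_buffers=buffers,
            seed=side["seed"],
            plane=side.get("plane", "xyz"),
            meta=side.get("meta", {}),
        )


def _iter_bn(module: nn.Module):
    """Yield (BatchNorm2d layer, name prefix) pairs inside a model."""
    stack = [module]
    while stack:
        m = stack.pop()
        if isinstance(m, nn.BatchNorm2d):
            yield m, m.gamma.name.rsplit(".gamma", 1)[0]
        for attr in ("layers", "body"):
            sub = getattr(m, attr, None)
            if isinstance(sub, list):
                stack.extend(sub)
            elif isinstance(sub, nn.Module):
                stack.append(sub)


def _to_batch(pairs: list[TrainingPair], idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([pairs[i].degraded.pixels for i in idx])[:, None]
    y = np.stack([pairs[i].target.pixels for i in idx])[:, None]
    return x, y


def split_pairs(pairs: list[TrainingPair], split: tuple[int, int], rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Shuffled train/validation index split at the configured ratio."""
    n = len(pairs)
    order = rng.permutation(n)
    n_train = int(round(n * split[0] / (split[0] + split[1])))
    return list(order[:n_train]), list(order[n_train:])


def train(
    dataset: list[TrainingPair],
    config: TrainConfig | None = None,
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
) -> tuple[Checkpoint, pd.DataFrame]:
    """Alternating adversarial training; returns a checkpoint and history.

    One discriminator update (real batch then generated batch) is
    followed by one generator update per step.  The history has one row
    per generator step with the discriminator loss, the adversarial
    value, the perceptual and pixel losses, the composite
    generator objective, and the running validation MSE (recomputed at
    every epoch boundary and at the final step).  Deterministic for a
    fixed seed on a fixed device.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    config = config or TrainConfig()
    config.validate()
    rng = np.random.default_rng([config.seed, 0x7261])

    train_idx, val_idx = split_pairs(dataset, config.split, rng)
    if not train_idx:
        raise ValueError("split left no training pairs")

    gen = Generator(gen_spec or GeneratorSpec(), seed=config.seed)
    disc = Discriminator(disc_spec or DiscriminatorSpec(), seed=config.seed)
    feats = FeatureExtractor(seed=config.seed)
    opt_g = nn.Adam(gen.params(), lr=config.learning_rate)
    opt_d = nn.Adam(disc.params(), lr=config.learning_rate)
    lam, beta = config.loss.lam, config.loss.beta
    scale = config.loss.intensity_scale

    def val_mse() -> float:
        """Validation pixel MSE on the configured loss intensity scale."""
        if not val_idx:
            return float("nan")
        errs = []
        for i in val_idx:
            x = dataset[i].degraded.pixels[None, None]
            y = dataset[i].target.pixels[None, None]
            out = gen.forward(x, training=False)
            errs.append(float(np.mean((scale * (out - y)) ** 2)))
        return float(np.mean(errs))

    rows = []
    step = 0
    batch = min(config.batch_size, len(train_idx))
    current_val = val_mse()
    done = False
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        for start in range(0, len(order) - batch + 1, batch):
            idx = np.asarray(train_idx)[order[start : start + batch]]
            x, y = _to_batch(dataset, idx)

            # --- discriminator step: maximize log D(real) + log(1 - D(fake))
            fake = gen.forward(x, training=True)
            disc.zero_grad()
            p_real = disc.forward(y, training=True)
            pr = np.clip(p_real, _PROB_EPS, 1 - _PROB_EPS)
            disc.backward(-1.0 / (pr * batch))  # d(-mean log p)/dp
            p_fake_d = disc.forward(fake, training=True)
            pf = np.clip(p_fake_d, _PROB_EPS, 1 - _PROB_EPS)
            disc.backward(1.0 / ((1.0 - pf) * batch))  # d(-mean log(1-p))/dp
            d_loss = float(-(np.mean(np.log(pr)) + np.mean(np.log(1.0 - pf))))
            opt_d.step()

            # --- generator step: minimize log(1 - D(fake)) + lam*L_X + beta*L_MSE
            fake = gen.forward(x, training=True)
            p_fake = disc.forward(fake, training=True)
            pf = np.clip(p_fake, _PROB_EPS, 1 - _PROB_EPS)
            disc.zero_grad()
            d_fake = disc.backward(-1.0 / ((1.0 - pf) * batch))
            disc.zero_grad()  # discard D parameter grads from the G pass

            fg = feats.forward(fake * scale)
            ft = feats.forward(y * scale)
            d_feat = feats.backward(2.0 * (fg - ft) / fg.size) * scale
            d_mse = 2.0 * scale * scale * (fake - y) / fake.size

            gen.zero_grad()
            gen.backward(d_fake + lam * d_feat + beta * d_mse)
            opt_g.step()

            l_gan = float(np.mean(np.log(np.clip(p_real, _PROB_EPS, 1 - _PROB_EPS))) + np.mean(np.log(1.0 - pf)))
            l_mse = float(np.mean((scale * (fake - y)) ** 2))
            l_x = float(np.mean((fg - ft) ** 2))
            g_adv = float(np.mean(np.log(1.0 - pf)))
            g_total = g_adv + lam * l_x + beta * l_mse
            if not all(math.isfinite(v) for v in (d_loss, g_total, l_gan, l_x)):
                raise TrainingFault(f"non-finite loss at step {step}: d={d_loss}, g={g_total}")
            step += 1
            rows.append(
                {
                    "step": step,
                    "epoch": epoch,
                    "d_loss": d_loss,
                    "l_gan": l_gan,
                    "g_adv": g_adv,
                    "l_x": l_x,
                    "l_mse": l_mse,
                    "g_total": g_total,
                    "val_mse": current_val,
                }
            )
            if config.max_steps is not None and step >= config.max_steps:
                done = True
                break
        current_val = val_mse()
        if rows:
            rows[-1]["val_mse"] = current_val
        if done:
            break

    history = pd.DataFrame(rows)
    ckpt = Checkpoint.from_generator(
        gen,
        seed=config.seed,
        plane=config.plane,
        meta={"steps": step, "n_train": len(train_idx), "n_val": len(val_idx)},
    )
    return ckpt, history


def correct(checkpoint: Checkpoint, image: SliceImage, histogram_match_to_input: bool = False) -> SliceImage:
    """Restore one degraded slice with a trained checkpoint."""
    gen = checkpoint.build()
    ts = gen.spec.total_stride
    h, w = image.pixels.shape
    if h % ts or w % ts:
        raise ValueError(f"image size {h}x{w} incompatible with total stride {ts}")
    out = gen.forward(image.pixels[None, None], training=False)[0, 0]
    restored = image.with_pixels(np.clip(out, 0.0, 1.0), suffix="-corr")
    if histogram_match_to_input:
        restored = histogram_match(restored, image)
    return restored
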