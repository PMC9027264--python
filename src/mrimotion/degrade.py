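"""Forward degradation model: blurred = sharp (*) K + N.

A blurred slice is the true 2-D convolution of the sharp slice with a
normalized motion kernel, optionally plus zero-mean additive Gaussian
noise, clipped back to unit range.  True convolution (kernel flipped)
is used, as implemented by :func:`scipy.ndimage.convolve`; with the
even 16x16 kernel canvas the convolution center is cell
``(grid_size // 2, grid_size // 2)``.  The positional shift an
off-center kernel induces is deliberately kept (kernels are not
recentered) and removed downstream by landmark registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .kernels import KernelFamily, MotionKernel
from .phantom import SliceImage

__all__ = ["DegradationConfig", "degrade", "degrade_batch"]

_BOUNDARY_MODES = {"reflect": "reflect", "constant-zero": "constant"}


@dataclass
class DegradationConfig:
    boundary: str = "reflect"
    noise_kind: str = "none"  # {"none", "additive-gaussian"}
    noise_sigma: float = 0.0

    def validate(self) -> None:
        if self.boundary not in _BOUNDARY_MODES:
            raise ValueError(f"boundary must be one of {sorted(_BOUNDARY_MODES)}, got {self.boundary!r}")
        if self.noise_kind not in ("none", "additive-gaussian"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def degrade(
    sharp: SliceImage,
    kernel: MotionKernel,
    config: DegradationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SliceImage:
    """Convolve a sharp slice with a normalized kernel (Gaussian noise optional)."""
    config = config or DegradationConfig()
    config.validate()
    if abs(kernel.weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"kernel is not normalized (sum={kernel.weights.sum()!r})")
    out = ndimage.convolve(sharp.pixels, kernel.weights, mode=_BOUNDARY_MODES[config.boundary], cval=0.0)
    if config.noise_kind == "additive-gaussian" and config.noise_sigma > 0:
        if rng is None:
            raise ValueError("additive noise requires a seeded rng")
        out = out + rng.normal(0.0, config.noise_sigma, size=out.shape)
    return sharp.with_pixels(np.clip(out, 0.0, 1.0), suffix="-blur")


def degrade_batch(
    sharps: list[SliceImage],
    family: KernelFamily,
    config: DegradationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[SliceImage, str]]:
    """Blur each slice with a kernel drawn uniformly at random from the family."""
    if len(family) == 0:
        raise ValueError("kernel family is empty")
    rng = np.random.default_rng() if rng is None else rng
    idx = rng.integers(0, len(family), size=len(sharps))
    out = []
    for sharp, i in zip(sharps, idx):
        k = family[int(i)]
        out.append((degrade(sharp, k, config=config, rng=rng), k.kernel_id))
    return out
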