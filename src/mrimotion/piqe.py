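"""Perception-based Image Quality Evaluator (PIQE), a no-reference score.

PIQE rates an image in [0, 100] (lower is better) from block-wise
analysis of mean-subtracted contrast-normalized (MSCN) coefficients:

1. Scale intensities to [0, 255] and pad by edge replication to a
   multiple of the 16-pixel block size.
2. Compute MSCN coefficients ``(I - mu) / (sigma + 1)`` where ``mu`` and
   ``sigma`` are the local Gaussian-weighted mean and standard deviation
   (7x7 window, sigma 7/6).
3. A block is *spatially active* when its MSCN variance exceeds 0.1;
   only active blocks are scored.
4. An active block shows a *noticeable artifact* (blockiness) when any
   6-pixel segment along one of its four edges has MSCN standard
   deviation below 0.1 (an implausibly flat edge run).
5. An active block is *noise-dominated* when its standard deviation is
   more than twice the distortion coefficient beta built from the ratio
   of center-columns to surround standard deviation.
6. Artifact blocks contribute ``1 - var``, noise blocks ``var``; the
   pooled score is ``100 * (sum + C) / (C + n_active)`` with C = 1,
   clipped to [0, 100].

Constants follow the published algorithm; a uniform image has no active
blocks and scores exactly 100.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .phantom import SliceImage

__all__ = ["piqe"]

BLOCK_SIZE = 16
ACTIVITY_THRESHOLD = 0.1
SEGMENT_STD_THRESHOLD = 0.1
SEGMENT_LENGTH = 6
POOLING_CONSTANT = 1.0
_GAUSS_SIGMA = 7.0 / 6.0
_GAUSS_RADIUS = 3  # 7x7 window


def _mscn(img255: np.ndarray) -> np.ndarray:
    mu = ndimage.gaussian_filter(img255, _GAUSS_SIGMA, radius=_GAUSS_RADIUS, mode="nearest")
    var = ndimage.gaussian_filter(img255 * img255, _GAUSS_SIGMA, radius=_GAUSS_RADIUS, mode="nearest") - mu * mu
    sigma = np.sqrt(np.abs(var))
    return (img255 - mu) / (sigma + 1.0)


def _edge_segments_flat(block: np.ndarray) -> bool:
    """True when any 6-pixel sliding segment on a block edge is near-constant."""
    edges = (block[0, :], block[-1, :], block[:, 0], block[:, -1])
    for edge in edges:
        windows = np.lib.stride_tricks.sliding_window_view(edge, SEGMENT_LENGTH)
        if np.any(windows.std(axis=1, ddof=1) < SEGMENT_STD_THRESHOLD):
            return True
    return False


def _noise_dominated(block: np.ndarray, block_var: float) -> bool:
    """Gaussian-noise check from the center/surround deviation ratio."""
    block_sigma = float(np.sqrt(block_var))
    n = block.shape[1]
    c1 = n // 2 - 1
    center = block[:, c1 : c1 + 2]
    surround = np.delete(block, [c1, c1 + 1], axis=1)
    s_sur = surround.std(ddof=1)
    cen_sur = center.std(ddof=1) / s_sur if s_sur > 0 else 0.0
    if not np.isfinite(cen_sur):
        cen_sur = 0.0
    denom = max(block_sigma, cen_sur)
    beta = abs(block_sigma - cen_sur) / denom if denom > 0 else 0.0
    return block_sigma > 2.0 * beta


def piqe(image: SliceImage | np.ndarray) -> float:
    """PIQE score in [0, 100] of a unit-range slice; lower is better."""
    pixels = image.pixels if isinstance(image, SliceImage) else np.asarray(image, dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("piqe expects a 2-D grayscale image")
    h, w = pixels.shape
    if h < BLOCK_SIZE or w < BLOCK_SIZE:
        raise ValueError(f"image must be at least one {BLOCK_SIZE}x{BLOCK_SIZE} block, got {pixels.shape}")

    img = pixels * 255.0
    pad_h = (-h) % BLOCK_SIZE
    pad_w = (-w) % BLOCK_SIZE
    if pad_h or pad_w:
        img = np.pad(img, ((0, pad_h), (0, pad_w)), mode="edge")

    mscn = _mscn(img)
    n_active = 0
    dist_scores = 0.0
    for i in range(0, img.shape[0], BLOCK_SIZE):
        for j in range(0, img.shape[1], BLOCK_SIZE):
            block = mscn[i : i + BLOCK_SIZE, j : j + BLOCK_SIZE]
            block_var = float(block.var(ddof=1))
            if block_var <= ACTIVITY_THRESHOLD:
                continue
            n_active += 1
            if _edge_segments_flat(block):
                dist_scores += 1.0 - block_var
            if _noise_dominated(block, block_var):
                dist_scores += block_var

    score = 100.0 * (dist_scores + POOLING_CONSTANT) / (POOLING_CONSTANT + n_active)
    return float(np.clip(score, 0.0, 100.0))
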