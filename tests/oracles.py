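"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (nested
loops, exhaustive enumeration) and never calls the implementation paths
it is used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_convolve2d(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True 2-D convolution with zero boundary, by direct summation.

    Uses the convention that the kernel center is cell ``size // 2``
    (matching the package's documented convention), i.e.
    ``out[i, j] = sum_{a, b} image[a, b] * kernel[i - a + cr, j - b + cc]``.
    """
    H, W = image.shape
    kh, kw = kernel.shape
    cr, cc = kh // 2, kw // 2
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for a in range(H):
                u = i - a + cr
                if not 0 <= u < kh:
                    continue
                for b in range(W):
                    v = j - b + cc
                    if 0 <= v < kw:
                        acc += image[a, b] * kernel[u, v]
            out[i, j] = acc
    return out


def path_is_valid(
    cells: list[tuple[int, int]],
    grid_size: int,
    connectivity: int,
    min_separation: float,
) -> bool:
    """Constraint check for a walk, written independently of the package."""
    k = len(cells)
    if k < 1 or len(set(cells)) != k:
        return False
    for (r, c) in cells:
        if not (0 <= r < grid_size and 0 <= c < grid_size):
            return False
    for i in range(1, k):
        dr = abs(cells[i][0] - cells[i - 1][0])
        dc = abs(cells[i][1] - cells[i - 1][1])
        if connectivity == 4 and dr + dc != 1:
            return False
        if connectivity == 8 and max(dr, dc) != 1:
            return False
        for j in range(i - 1):
            if math.dist(cells[i], cells[j]) < min_separation:
                return False
    return True


def enumerate_valid_paths(
    k: int,
    grid_size: int,
    connectivity: int = 4,
    min_separation: float = 1.5,
) -> set[tuple[tuple[int, int], ...]]:
    """All valid k-cell walks, by exhaustive depth-first enumeration."""
    if connectivity == 4:
        offsets = ((-1, 0), (1, 0), (0, -1), (0, 1))
    else:
        offsets = tuple((dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0))
    found: set[tuple[tuple[int, int], ...]] = set()

    def extend(path: list[tuple[int, int]]) -> None:
        if len(path) == k:
            found.add(tuple(path))
            return
        r0, c0 = path[-1]
        for dr, dc in offsets:
            nxt = (r0 + dr, c0 + dc)
            if path_is_valid(path + [nxt], grid_size, connectivity, min_separation):
                extend(path + [nxt])

    for r, c in itertools.product(range(grid_size), repeat=2):
        extend([(r, c)])
    return found


def generator_param_count(
    base: int,
    n_encode: int,
    n_res: int,
    n_decode: int,
    first_k: int,
    other_k: int,
    in_ch: int = 1,
) -> int:
    """Closed-form parameter count of the restoration network.

    Counts conv weights + biases and batchnorm gain/offset for the
    encode blocks (filters b, 2b, then 4b), residual blocks, mirrored
    transposed-conv decode blocks, and the zero-initialized head.
    """
    enc = [base, 2 * base] + [4 * base] * (n_encode - 2)
    enc = enc[:n_encode]
    total = 0
    prev = in_ch
    for i, f in enumerate(enc):
        kk = first_k if i == 0 else other_k
        total += prev * f * kk * kk + f  # conv
        total += 2 * f  # batchnorm
        prev = f
    for _ in range(n_res):
        for _ in range(2):
            total += prev * prev * other_k * other_k + prev + 2 * prev
    for f in reversed(enc[:-1]):
        total += prev * f * other_k * other_k + f + 2 * f
        prev = f
    total += prev * in_ch * first_k * first_k + in_ch  # head conv (no BN)
    return total
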