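"""Curvilinear motion-blur kernels from constrained random walks.

In-scanner head motion on short time scales follows simple curves
(rotation, shaking, nodding).  The point-spread functions modelling such
motion are therefore short, continuous, non-self-approaching paths on a
small grid.  A walk starts at a uniformly random cell of a 16x16 grid and
extends one admissible step at a time; a step is admissible when it stays
on the grid, moves to an adjacent cell, and keeps a minimum Euclidean
separation from every previously visited cell except its immediate
predecessor.  When a walk runs out of admissible moves it is aborted and
retried from scratch, up to a fixed attempt budget (trial and error rather
than backtracking).  Rasterizing a path with uniform weights gives a
normalized convolution kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelGenerationError",
    "KernelPath",
    "MotionKernel",
    "KernelFamily",
    "generate_walk",
    "rasterize",
    "generate_family",
    "delta_kernel",
    "save_family",
    "load_family",
]

_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


class KernelGenerationError(RuntimeError):
    """Raised when no valid walk is found within the attempt budget."""

    def __init__(self, k: int, attempts: int):
        super().__init__(f"no valid walk of length {k} found in {attempts} attempts")
        self.k = k
        self.attempts = attempts


@dataclass
class KernelPath:
    """An ordered self-avoiding path of grid cells."""

    cells: list[tuple[int, int]]
    grid_size: int = 16

    @property
    def k(self) -> int:
        return len(self.cells)

    def validate(self, connectivity: int = 8, min_separation: float = 1.5, max_length: int | None = None) -> None:
        if self.k < 1:
            raise ValueError("path must contain at least one cell")
        if max_length is not None and self.k > max_length:
            raise ValueError(f"path length {self.k} exceeds max_length {max_length}")
        for (r, c) in self.cells:
            if not (0 <= r < self.grid_size and 0 <= c < self.grid_size):
                raise ValueError(f"cell ({r}, {c}) outside [0, {self.grid_size}) grid")
        if len(set(self.cells)) != self.k:
            raise ValueError("path revisits a cell")
        cells = np.asarray(self.cells, dtype=np.float64)
        for i in range(1, self.k):
            dr = abs(self.cells[i][0] - self.cells[i - 1][0])
            dc = abs(self.cells[i][1] - self.cells[i - 1][1])
            cheb = max(dr, dc)
            manh = dr + dc
            if connectivity == 8 and cheb != 1:
                raise ValueError(f"step {i} not 8-adjacent")
            if connectivity == 4 and manh != 1:
                raise ValueError(f"step {i} not 4-adjacent")
            # separation from all non-consecutive earlier cells
            if i >= 2:
                d = np.hypot(*(cells[: i - 1] - cells[i]).T)
                if d.min() < min_separation:
                    raise ValueError(f"step {i} approaches a visited cell closer than {min_separation}")


@dataclass
class MotionKernel:
    """A rasterized walk: nonnegative weights on the path cells, summing to 1."""

    path: KernelPath
    weights: np.ndarray
    kernel_id: str = ""

    def validate(self) -> None:
        w = self.weights
        if w.shape != (self.path.grid_size, self.path.grid_size):
            raise ValueError("weight matrix does not match the grid size")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        support = {tuple(ix) for ix in np.argwhere(w > 0)}
        if support != set(self.path.cells):
            raise ValueError("nonzero weights do not coincide with path cells")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {w.sum()!r}, expected 1")


@dataclass
class KernelFamily:
    """A list of kernels plus the configuration that generated them."""

    kernels: list[MotionKernel]
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.kernels)

    def __getitem__(self, i: int) -> MotionKernel:
        return self.kernels[i]


def _admissible_moves(
    path: list[tuple[int, int]],
    grid_size: int,
    offsets: tuple,
    min_separation: float,
    memory: int | None,
) -> list[tuple[int, int]]:
    r0, c0 = path[-1]
    visited = path if memory is None else path[-(memory + 1) :]
    out = []
    for dr, dc in offsets:
        r, c = r0 + dr, c0 + dc
        if not (0 <= r < grid_size and 0 <= c < grid_size):
            continue
        ok = True
        for (pr, pc) in visited[:-1]:  # all but the immediate predecessor
            if (pr - r) ** 2 + (pc - c) ** 2 < min_separation**2:
                ok = False
                break
        if ok and (r, c) not in visited:
            out.append((r, c))
    return out


def generate_walk(
    k: int,
    grid_size: int = 16,
    connectivity: int = 8,
    min_separation: float = 1.5,
    max_attempts: int = 256,
    rng: np.random.Generator | None = None,
    memory: int | None = None,
) -> KernelPath:
    """Draw one valid self-avoiding walk of exactly ``k`` cells.

    The start cell is uniform over the grid and every step is uniform over
    the currently admissible moves; an attempt with no admissible move is
    aborted and restarted.  Raises :class:`KernelGenerationError` after
    ``max_attempts`` failed attempts.
    """
    if not 1 <= k <= grid_size**2:
        raise ValueError(f"k must be in [1, {grid_size ** 2}], got {k}")
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    rng = np.random.default_rng() if rng is None else rng
    offsets = _OFFSETS_8 if connectivity == 8 else _OFFSETS_4

    for _ in range(max_attempts):
        start = (int(rng.integers(grid_size)), int(rng.integers(grid_size)))
        path = [start]
        while len(path) < k:
            moves = _admissible_moves(path, grid_size, offsets, min_separation, memory)
            if not moves:
                break
            path.append(moves[int(rng.integers(len(moves)))])
        if len(path) == k:
            return KernelPath(cells=path, grid_size=grid_size)
    raise KernelGenerationError(k, max_attempts)


def rasterize(path: KernelPath, weighting: str = "uniform") -> MotionKernel:
    """Turn a walk into a normalized convolution kernel (1/k per cell)."""
    if weighting != "uniform":
        raise ValueError(f"unsupported weighting {weighting!r}")
    w = np.zeros((path.grid_size, path.grid_size), dtype=np.float64)
    for (r, c) in path.cells:
        w[r, c] = 1.0 / path.k
    return MotionKernel(path=path, weights=w)


def delta_kernel(grid_size: int = 16) -> MotionKernel:
    """The identity kernel: unit mass at the convolution center cell.

    For an even-sized canvas the center convention is ``grid_size // 2``
    (matching :func:`scipy.ndimage.convolve` with its default origin), so
    convolving with this kernel reproduces the input exactly.
    """
    c = grid_size // 2
    path = KernelPath(cells=[(c, c)], grid_size=grid_size)
    mk = rasterize(path)
    mk.kernel_id = f"delta-{grid_size}"
    return mk


def recenter_kernel(kernel: MotionKernel) -> MotionKernel:
    """Translate a kernel so its weight centroid sits at the convolution center.

    Convolution with an off-center kernel shifts image content; the
    pipeline removes that shift by landmark registration.  For uses that
    need shift-free blurring directly (e.g. supervised pairs without a
    registration stage), this returns a copy whose path is translated so
    the mass centroid is as close as possible to ``(grid_size // 2,
    grid_size // 2)``, with the translation clamped to keep every cell
    on the grid.
    """
    gs = kernel.path.grid_size
    cells = np.asarray(kernel.path.cells)
    centroid = cells.mean(axis=0)
    want = np.array([gs // 2, gs // 2], dtype=np.float64)
    delta = np.round(want - centroid).astype(int)
    for axis in (0, 1):
        lo, hi = cells[:, axis].min(), cells[:, axis].max()
        delta[axis] = int(np.clip(delta[axis], -lo, gs - 1 - hi))
    new_cells = [(int(r + delta[0]), int(c + delta[1])) for r, c in kernel.path.cells]
    new_path = KernelPath(cells=new_cells, grid_size=gs)
    out = rasterize(new_path)
    out.kernel_id = kernel.kernel_id + "-centered" if kernel.kernel_id else ""
    return out


def generate_family(
    n: int,
    length_min: int = 1,
    length_max: int = 15,
    grid_size: int = 16,
    connectivity: int = 8,
    min_separation: float = 1.5,
    max_attempts: int = 256,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    memory: int | None = None,
) -> KernelFamily:
    """Generate ``n`` kernels with lengths uniform on [length_min, length_max]."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 1 <= length_min <= length_max <= grid_size**2:
        raise ValueError(f"need 1 <= length_min <= length_max <= {grid_size ** 2}")
    if rng is None:
        rng = np.random.default_rng(seed)
    config = {
        "n": n,
        "length_min": length_min,
        "length_max": length_max,
        "grid_size": grid_size,
        "connectivity": connectivity,
        "min_separation": min_separation,
        "max_attempts": max_attempts,
        "seed": seed,
        "memory": memory,
    }
    kernels = []
    for i in range(n):
        k = int(rng.integers(length_min, length_max + 1))
        path = generate_walk(
            k,
            grid_size=grid_size,
            connectivity=connectivity,
            min_separation=min_separation,
            max_attempts=max_attempts,
            rng=rng,
            memory=memory,
        )
        mk = rasterize(path)
        mk.kernel_id = f"rw-{grid_size}x{grid_size}-k{k}-{i:06d}"
        kernels.append(mk)
    return KernelFamily(kernels=kernels, config=config)


def save_family(family: KernelFamily, path) -> None:
    """Persist a family to HDF5 (ragged paths via offsets, stacked weights)."""
    import h5py

    cells = np.concatenate([np.asarray(k.path.cells, dtype=np.int32).reshape(-1, 2) for k in family.kernels]) if len(family) else np.zeros((0, 2), np.int32)
    lengths = np.asarray([k.path.k for k in family.kernels], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    weights = np.stack([k.weights for k in family.kernels]) if len(family) else np.zeros((0, 0, 0))
    with h5py.File(path, "w") as f:
        f.create_dataset("cells", data=cells)
        f.create_dataset("offsets", data=offsets)
        f.create_dataset("weights", data=weights)
        f.create_dataset("kernel_ids", data=np.array([k.kernel_id for k in family.kernels], dtype=h5py.string_dtype()))
        f.attrs["config"] = json.dumps(family.config)


def load_family(path) -> KernelFamily:
    import h5py

    with h5py.File(path, "r") as f:
        cells = f["cells"][()]
        offsets = f["offsets"][()]
        weights = f["weights"][()]
        ids = [s.decode() if isinstance(s, bytes) else s for s in f["kernel_ids"][()]]
        config = json.loads(f.attrs["config"])
    kernels = []
    gs = config["grid_size"]
    for i in range(len(ids)):
        cc = [tuple(map(int, rc)) for rc in cells[offsets[i] : offsets[i + 1]]]
        kernels.append(MotionKernel(path=KernelPath(cells=cc, grid_size=gs), weights=weights[i], kernel_id=ids[i]))
    return KernelFamily(kernels=kernels, config=config)
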