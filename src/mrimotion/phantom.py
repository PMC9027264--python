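"""Synthetic 256x256 brain-like slice phantoms.

Real studies of motion-blur correction train on T1-weighted scan slices.
This module produces deterministic, seeded stand-ins with the gross
features such slices expose to the rest of the pipeline: a bright
skull-like rim, mid-intensity tissue with internal structure, dark
ventricle-like cavities, and a dark background frame.  The geometry is
deliberately plane-dependent (sagittal / axial / coronal) so per-plane
model experiments can be exercised without any data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

PLANES = ("sagittal", "axial", "coronal")

__all__ = ["PLANES", "SliceImage", "make_phantom", "make_phantom_set", "write_slices"]


@dataclass
class SliceImage:
    """A 2-D grayscale slice with unit-range intensities and a plane tag."""

    pixels: np.ndarray
    plane: str = "axial"
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.validate()

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def validate(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D intensity grid, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}, got {self.plane!r}")

    def with_pixels(self, pixels: np.ndarray, suffix: str = "") -> "SliceImage":
        """A copy carrying new pixel data, optionally with an id suffix."""
        return replace(self, pixels=pixels, id=self.id + suffix)


# Per-plane geometry: (rim semi-axes as size fractions, rotation degrees,
# ventricle layout).  Chosen so the three planes are visually and
# statistically distinct without pretending to anatomy.
_PLANE_GEOMETRY = {
    "sagittal": {"axes": (0.40, 0.33), "vents": [((0.05, 0.02), (0.10, 0.05), 25.0)]},
    "axial": {
        "axes": (0.36, 0.30),
        "vents": [((-0.02, -0.06), (0.09, 0.03), 70.0), ((-0.02, 0.06), (0.09, 0.03), -70.0)],
    },
    "coronal": {"axes": (0.33, 0.37), "vents": [((0.0, -0.05), (0.08, 0.025), 85.0), ((0.0, 0.05), (0.08, 0.025), -85.0)]},
}


def _ellipse_mask(size: int, center: tuple[float, float], axes: tuple[float, float], angle_deg: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr = rr - center[0]
    dc = cc - center[1]
    th = np.deg2rad(angle_deg)
    u = np.cos(th) * dr + np.sin(th) * dc
    v = -np.sin(th) * dr + np.cos(th) * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def make_phantom(seed: int, plane: str = "axial", size: int = 256) -> SliceImage:
    """Generate one deterministic brain-like slice.

    Parameters
    ----------
    seed
        Any non-negative integer; the same ``(seed, plane, size)`` triple
        always yields a bit-identical image.
    plane
        One of ``sagittal`` / ``axial`` / ``coronal``; controls the rim
        aspect ratio and internal structure layout.
    size
        Side length in pixels, at least 64.
    """
    if size < 64:
        raise ValueError(f"phantom size must be >= 64, got {size}")
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {PLANES}, got {plane!r}")

    geom = _PLANE_GEOMETRY[plane]
    rng = np.random.default_rng([int(seed), PLANES.index(plane), int(size)])
    c = (size - 1) / 2.0

    # Per-seed jitter of geometry and intensity bands.
    jit = rng.uniform(0.94, 1.06, size=2)
    angle = rng.uniform(-12.0, 12.0)
    center = (c + rng.uniform(-3, 3) * size / 256, c + rng.uniform(-3, 3) * size / 256)
    a_rim = (geom["axes"][0] * size * jit[0], geom["axes"][1] * size * jit[1])
    rim_hi = rng.uniform(0.82, 0.95)
    tissue_lo = rng.uniform(0.45, 0.55)
    vent_lo = rng.uniform(0.08, 0.15)

    img = np.zeros((size, size), dtype=np.float64)
    rim = _ellipse_mask(size, center, a_rim, angle)
    inner = _ellipse_mask(size, center, (a_rim[0] * 0.88, a_rim[1] * 0.88), angle)
    img[rim] = rim_hi
    img[inner] = tissue_lo

    # Mid-intensity cortical band between rim and tissue.
    band = rim & ~_ellipse_mask(size, center, (a_rim[0] * 0.95, a_rim[1] * 0.95), angle)
    img[band] = rim_hi

    # Ventricle-like dark cavities, plane-specific layout.
    for (off, ax, vang) in geom["vents"]:
        vc = (center[0] + off[0] * size, center[1] + off[1] * size)
        vm = _ellipse_mask(size, vc, (ax[0] * size, ax[1] * size), angle + vang)
        img[vm] = vent_lo

    # Blobs of tissue-contrast texture: landmarks for keypoint detection.
    n_blobs = int(rng.integers(6, 12))
    for _ in range(n_blobs):
        br = rng.uniform(0.03, 0.10) * size
        theta = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.0, 0.55)
        bc = (center[0] + rad * a_rim[0] * 0.8 * np.sin(theta), center[1] + rad * a_rim[1] * 0.8 * np.cos(theta))
        bm = _ellipse_mask(size, bc, (br, br * rng.uniform(0.5, 1.0)), rng.uniform(0, 180)) & inner
        img[bm] = np.clip(tissue_lo + rng.uniform(-0.22, 0.28), 0.02, 0.98)

    img = ndimage.gaussian_filter(img, sigma=1.2)

    # Low-amplitude smoothed noise texture inside the head only.
    tex = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=1.0)
    img = img + 0.015 * tex * rim

    # Hard dark frame: outer 5% margin forced to near zero.
    margin = max(1, int(round(0.05 * size)))
    frame = np.zeros((size, size), dtype=bool)
    frame[:margin, :] = frame[-margin:, :] = True
    frame[:, :margin] = frame[:, -margin:] = True
    img[frame] = np.minimum(img[frame], 0.01)

    return SliceImage(np.clip(img, 0.0, 1.0), plane=plane, id=f"phantom-{plane}-s{int(seed)}-{size}")


def make_phantom_set(n_per_plane: int, seed: int = 0, size: int = 256) -> list[SliceImage]:
    """Generate ``n_per_plane`` phantoms for each of the three planes."""
    if n_per_plane < 1:
        raise ValueError(f"n_per_plane must be >= 1, got {n_per_plane}")
    out: list[SliceImage] = []
    for plane in PLANES:
        for i in range(n_per_plane):
            ph = make_phantom(seed=int(seed) * 100_003 + i, plane=plane, size=size)
            ph.id = f"{ph.id}-i{i}"
            out.append(ph)
    return out


def write_slices(slices: list[SliceImage], out_dir, manifest_name: str = "manifest.csv") -> pd.DataFrame:
    """Write slices as 8-bit grayscale PNGs plus a manifest CSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in slices:
        path = out / f"{s.id}.png"
        Image.fromarray(np.round(s.pixels * 255.0).astype(np.uint8), mode="L").save(path)
        rows.append({"id": s.id, "plane": s.plane, "path": str(path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / manifest_name, index=False)
    return manifest
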