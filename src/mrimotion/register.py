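"""Landmark alignment and intensity matching of blurred/sharp pairs.

Convolving with an off-center kernel shifts the image content, which
would corrupt the blurred/sharp pairing used for supervised training.
Alignment detects oriented keypoints with binary descriptors (ORB) in
both images, matches them exhaustively (brute-force Hamming matching
with cross-checking), fits a robust translation by inlier consensus,
warps the blurred image into the sharp frame, and finally remaps its
intensity histogram onto the sharp image's.  The consensus search
enumerates every match as a candidate translation, scores candidates by
inlier count (ties broken by mean inlier residual), and refines with the
inlier mean; it is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, feature, measure, transform

from .phantom import SliceImage

__all__ = [
    "AlignmentFailure",
    "PlanarTransform",
    "TrainingPair",
    "detect_and_match",
    "estimate_transform",
    "histogram_match",
    "align_pair",
]


class AlignmentFailure(RuntimeError):
    """Too few landmark matches to fit the requested transform."""

    def __init__(self, n_matches: int, needed: int):
        super().__init__(f"alignment needs >= {needed} matches, got {n_matches}")
        self.n_matches = n_matches


@dataclass
class PlanarTransform:
    """A translation (optionally similarity) mapping moving -> fixed frame."""

    kind: str = "translation"  # {"translation", "similarity"}
    shift: tuple[float, float] = (0.0, 0.0)  # (d_row, d_col)
    rotation: float | None = None  # degrees
    scale: float | None = None

    def validate(self) -> None:
        vals = [*self.shift] + [v for v in (self.rotation, self.scale) if v is not None]
        if not np.all(np.isfinite(vals)):
            raise ValueError("transform parameters must be finite")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.shift == (0.0, 0.0)
            and (self.rotation in (None, 0.0))
            and (self.scale in (None, 1.0))
        )


@dataclass
class TrainingPair:
    """An aligned, histogram-matched (degraded, sharp) slice pair."""

    degraded: SliceImage
    target: SliceImage
    transform: PlanarTransform = field(default_factory=PlanarTransform)
    status: str = "ok"  # {"ok", "failed"}
    kernel_id: str = ""
    plane: str = "axial"
    split: str = ""  # {"", "train", "validation", "test"}
    provenance: dict = field(default_factory=dict)  # morph specs, seeds, source ids


def detect_and_match(
    moving: SliceImage,
    fixed: SliceImage,
    n_keypoints: int = 500,
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """ORB keypoints + exhaustive Hamming matching, best matches first.

    Returns ``(moving_point, fixed_point, descriptor_distance)`` triples
    with points as (row, col); an empty list when either image yields no
    features (e.g. constant images).
    """
    if moving.pixels.shape != fixed.pixels.shape:
        raise ValueError("moving and fixed images must share a shape")
    kps = []
    for img in (moving, fixed):
        orb = feature.ORB(n_keypoints=n_keypoints)
        try:
            orb.detect_and_extract(img.pixels)
        except (RuntimeError, ValueError):
            return []
        if orb.keypoints.shape[0] == 0:
            return []
        kps.append((orb.keypoints, orb.descriptors))
    (kp_m, d_m), (kp_f, d_f) = kps
    matches = feature.match_descriptors(d_m, d_f, cross_check=True)
    if matches.shape[0] == 0:
        return []
    dist = np.mean(d_m[matches[:, 0]] != d_f[matches[:, 1]], axis=1)
    order = np.argsort(dist, kind="stable")
    return [(kp_m[i], kp_f[j], float(dist[n])) for n, (i, j) in zip(order, matches[order])]


def estimate_transform(
    matches: list[tuple[np.ndarray, np.ndarray, float]],
    kind: str = "translation",
    inlier_threshold: float = 1.0,
    seed: int = 0,
) -> PlanarTransform:
    """Robust inlier-consensus fit of a planar transform from matches.

    For translations every match proposes a candidate shift and all
    candidates are scored deterministically; the similarity fit uses a
    seeded RANSAC over skimage's SimilarityTransform.
    """
    if kind == "translation":
        if len(matches) < 1:
            raise AlignmentFailure(len(matches), 1)
        mv = np.asarray([m[0] for m in matches], dtype=np.float64)
        fx = np.asarray([m[1] for m in matches], dtype=np.float64)
        shifts = fx - mv
        best = None
        for cand in shifts:
            resid = np.hypot(*(shifts - cand).T)
            inliers = resid <= inlier_threshold
            score = (int(inliers.sum()), -float(resid[inliers].mean()))
            if best is None or score > best[0]:
                best = (score, inliers)
        refined = shifts[best[1]].mean(axis=0)
        return PlanarTransform(kind="translation", shift=(float(refined[0]), float(refined[1])))
    if kind == "similarity":
        if len(matches) < 2:
            raise AlignmentFailure(len(matches), 2)
        mv = np.asarray([m[0] for m in matches])[:, ::-1]  # (x, y) for skimage
        fx = np.asarray([m[1] for m in matches])[:, ::-1]
        model, _ = measure.ransac(
            (mv, fx),
            transform.SimilarityTransform,
            min_samples=2,
            residual_threshold=inlier_threshold,
            max_trials=500,
            rng=seed,
        )
        if model is None:
            raise AlignmentFailure(len(matches), 2)
        dx, dy = model.translation
        return PlanarTransform(
            kind="similarity",
            shift=(float(dy), float(dx)),
            rotation=float(np.rad2deg(model.rotation)),
            scale=float(model.scale),
        )
    raise ValueError(f"unknown transform kind {kind!r}")


def histogram_match(source: SliceImage, reference: SliceImage) -> SliceImage:
    """Monotone intensity remap giving source the reference's histogram."""
    if source.pixels.shape != reference.pixels.shape:
        raise ValueError("source and reference must share a shape")
    out = exposure.match_histograms(source.pixels, reference.pixels)
    return source.with_pixels(np.clip(out, 0.0, 1.0))


def _warp(image: SliceImage, tf: PlanarTransform) -> SliceImage:
    if tf.is_identity:
        return image
    if tf.kind == "translation":
        out = ndimage.shift(image.pixels, shift=tf.shift, order=1, mode="nearest")
    else:
        sk = transform.SimilarityTransform(
            scale=tf.scale or 1.0,
            rotation=np.deg2rad(tf.rotation or 0.0),
            translation=(tf.shift[1], tf.shift[0]),
        )
        out = transform.warp(image.pixels, sk.inverse, order=1, mode="edge")
    return image.with_pixels(np.clip(out, 0.0, 1.0))


def align_pair(
    blurred: SliceImage,
    sharp: SliceImage,
    kind: str = "translation",
    n_keypoints: int = 500,
    inlier_threshold: float = 1.0,
) -> TrainingPair:
    """Warp ``blurred`` onto ``sharp``'s frame and match its histogram.

    On alignment failure (no usable landmarks) the identity transform is
    used and the pair is flagged ``status="failed"`` rather than raising.
    """
    matches = detect_and_match(blurred, sharp, n_keypoints=n_keypoints)
    try:
        tf = estimate_transform(matches, kind=kind, inlier_threshold=inlier_threshold)
        status = "ok"
    except AlignmentFailure:
        tf, status = PlanarTransform(kind=kind), "failed"
    aligned = histogram_match(_warp(blurred, tf), sharp)
    return TrainingPair(degraded=aligned, target=sharp, transform=tf, status=status, plane=sharp.plane)
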