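"""Full-reference quality metrics, PSNR-level binning, and report tables.

Intensities live in unit range throughout the package, so RMSE is on the
[0, 1] scale and for unit-range images PSNR = -20*log10(RMSE).  RMSE on
a [0, 255] scale is the unit-range value times 255; PSNR is identical
under either convention when the peak is scaled accordingly, and both
conventions are exposed.  Identical pairs have infinite PSNR, reported
as a 99 dB sentinel in tabular output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import SliceImage
from .piqe import piqe  # re-exported for a single metrics surface

__all__ = ["rmse", "psnr", "piqe", "PSNR_SENTINEL_DB", "PSNR_LEVELS", "bin_by_psnr", "QualityReport", "build_report"]

PSNR_SENTINEL_DB = 99.0

# Degradation-level bins as printed in evaluation tables: half-open
# intervals, with 20 dB itself falling in the top bin.
PSNR_LEVELS = ("<17", "[17, 18)", "[18, 19)", "[19, 20)", ">20")
_LEVEL_EDGES = (17.0, 18.0, 19.0, 20.0)


def _pixels(a) -> np.ndarray:
    return a.pixels if isinstance(a, SliceImage) else np.asarray(a, dtype=np.float64)


def rmse(a, b, scale: float = 1.0) -> float:
    """Root-mean-square intensity difference; ``scale=255`` for 8-bit units."""
    pa, pb = _pixels(a), _pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    return float(np.sqrt(np.mean((pa - pb) ** 2))) * scale


def psnr(a, b, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    if peak <= 0:
        raise ValueError("peak must be > 0")
    pa, pb = _pixels(a), _pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    mse = float(np.mean((pa - pb) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def psnr_level(value: float) -> str:
    """Map a PSNR in dB to its printed degradation-level label."""
    if value < _LEVEL_EDGES[0]:
        return PSNR_LEVELS[0]
    for lo, hi, label in zip(_LEVEL_EDGES[:-1], _LEVEL_EDGES[1:], PSNR_LEVELS[1:-1]):
        if lo <= value < hi:
            return label
    return PSNR_LEVELS[-1]


def bin_by_psnr(pairs: list[tuple]) -> dict[str, list[int]]:
    """Group (degraded, target) pairs by the degraded image's PSNR level.

    Returns a mapping from level label to the indices of pairs in it;
    every pair is assigned to exactly one level.
    """
    if not pairs:
        raise ValueError("bin_by_psnr requires a nonempty pair list")
    groups: dict[str, list[int]] = {label: [] for label in PSNR_LEVELS}
    for i, (deg, tgt) in enumerate(pairs):
        groups[psnr_level(psnr(deg, tgt))].append(i)
    return groups


@dataclass
class QualityReport:
    """Per-image metric rows plus per-level aggregate table."""

    per_image: pd.DataFrame
    per_bin: pd.DataFrame
    reduction_mode: str = "mean_of_ratios"

    def to_csv(self, per_image_path, per_bin_path) -> None:
        self.per_image.to_csv(per_image_path, index=False)
        self.per_bin.to_csv(per_bin_path, index=False)


def _cap(v: float) -> float:
    return min(v, PSNR_SENTINEL_DB)


def build_report(rows: list[dict] | pd.DataFrame, reduction_mode: str = "mean_of_ratios") -> QualityReport:
    """Aggregate per-image metrics into the evaluation-table layout.

    ``rows`` must carry ``image_id`` plus degraded/corrected values for
    whichever of rmse/psnr/piqe were measured.  Reduction% is the
    per-image mean of ``(m_deg - m_corr)/m_deg * 100`` by default
    (``ratio_of_means`` aggregates means first); Gain is the mean of
    per-image PSNR differences with infinities capped at the sentinel.
    """
    if reduction_mode not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown reduction_mode {reduction_mode!r}")
    df = pd.DataFrame(rows).copy()
    if df.empty:
        raise ValueError("no metric rows given")
    if "psnr_degraded" in df:
        df["level"] = [psnr_level(v) for v in df["psnr_degraded"]]
    else:
        df["level"] = "all"

    bin_rows = []
    for label in (list(PSNR_LEVELS) if "psnr_degraded" in df else ["all"]):
        sub = df[df["level"] == label]
        if sub.empty:
            continue  # absent rows, not errors
        row: dict = {"level": label, "n": len(sub)}
        for metric in ("rmse", "psnr", "piqe"):
            dcol, ccol = f"{metric}_degraded", f"{metric}_corrected"
            if dcol not in sub:
                continue
            deg = sub[dcol].astype(float)
            if metric == "psnr":
                deg = deg.map(_cap)
            row[f"{metric}_degraded_mean"] = deg.mean()
            row[f"{metric}_degraded_std"] = deg.std(ddof=1) if len(sub) > 1 else 0.0
            if ccol in sub:
                corr = sub[ccol].astype(float)
                if metric == "psnr":
                    corr = corr.map(_cap)
                row[f"{metric}_corrected_mean"] = corr.mean()
                row[f"{metric}_corrected_std"] = corr.std(ddof=1) if len(sub) > 1 else 0.0
                if metric in ("rmse", "piqe"):
                    if reduction_mode == "mean_of_ratios":
                        ratios = (deg - corr) / deg.where(deg != 0, np.nan) * 100.0
                        row[f"{metric}_reduction_pct"] = float(ratios.mean(skipna=True))
                    else:
                        row[f"{metric}_reduction_pct"] = float((deg.mean() - corr.mean()) / deg.mean() * 100.0)
                else:
                    row["gain_db"] = float((corr - deg).mean())
        bin_rows.append(row)
    return QualityReport(per_image=df, per_bin=pd.DataFrame(bin_rows), reduction_mode=reduction_mode)
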