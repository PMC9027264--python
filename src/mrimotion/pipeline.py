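"""End-to-end orchestration: slices -> morphs -> blur -> aligned pairs -> report.

One global seed fans out to per-stage seeds, so two runs of the same
configuration produce identical kernel families, dataset manifests and
metric reports.  Every training pair carries full provenance: source
slice id, morph specs, kernel id, recovered transform, plane tag and
split assignment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .degrade import DegradationConfig, degrade
from .kernels import KernelFamily, generate_family
from .metrics import QualityReport, build_report, piqe, psnr, rmse
from .model import Checkpoint, DiscriminatorSpec, GeneratorSpec, TrainConfig, correct
from .morph import augment
from .phantom import PLANES, SliceImage
from .register import TrainingPair, align_pair

__all__ = [
    "KernelConfig",
    "MorphConfig",
    "RegistrationConfig",
    "PhantomConfig",
    "MetricsConfig",
    "PipelineConfig",
    "build_dataset",
    "dataset_manifest",
    "evaluate_run",
    "io_read_slices",
    "write_pairs",
    "read_pairs",
]


@dataclass
class KernelConfig:
    n: int = 200
    length_min: int = 1
    length_max: int = 15
    grid_size: int = 16
    connectivity: int = 8
    min_separation: float = 1.5
    max_attempts: int = 256


@dataclass
class MorphConfig:
    n_morphs: int = 4
    stretches_per_variant: int = 1
    radius_range: tuple[float, float] = (16.0, 64.0)
    margin: float = 16.0
    epsilon: float = 0.2


@dataclass
class RegistrationConfig:
    kind: str = "translation"
    n_keypoints: int = 500
    inlier_threshold: float = 1.0


@dataclass
class PhantomConfig:
    n_per_plane: int = 2
    size: int = 256


@dataclass
class MetricsConfig:
    reduction_mode: str = "mean_of_ratios"
    histogram_match_outputs: bool = True


@dataclass
class PipelineConfig:
    """All stage configurations plus the global seed and output root."""

    seed: int = 0
    out_dir: str = "runs/default"
    phantoms: PhantomConfig = field(default_factory=PhantomConfig)
    kernels: KernelConfig = field(default_factory=KernelConfig)
    morph: MorphConfig = field(default_factory=MorphConfig)
    degradation: DegradationConfig = field(default_factory=DegradationConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def rebuild(dc_type, value):
            if value is None:
                return dc_type()
            kwargs = {}
            for f in fields(dc_type):
                if f.name not in value:
                    continue
                v = value[f.name]
                if is_dataclass(f.type) if isinstance(f.type, type) else False:
                    v = rebuild(f.type, v)
                elif isinstance(v, list):
                    v = tuple(v)
                elif isinstance(v, dict) and f.name in _NESTED:
                    v = rebuild(_NESTED[f.name], v)
                kwargs[f.name] = v
            return dc_type(**kwargs)

        return rebuild(cls, data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


from .model import LossSpec  # noqa: E402  (nested-config rebuild table)

_NESTED = {
    "phantoms": PhantomConfig,
    "kernels": KernelConfig,
    "morph": MorphConfig,
    "degradation": DegradationConfig,
    "registration": RegistrationConfig,
    "generator": GeneratorSpec,
    "discriminator": DiscriminatorSpec,
    "training": TrainConfig,
    "metrics": MetricsConfig,
    "loss": LossSpec,
}


def make_family(config: PipelineConfig) -> KernelFamily:
    """The kernel family a pipeline run uses, seeded from the global seed."""
    kc = config.kernels
    return generate_family(
        kc.n,
        length_min=kc.length_min,
        length_max=kc.length_max,
        grid_size=kc.grid_size,
        connectivity=kc.connectivity,
        min_separation=kc.min_separation,
        max_attempts=kc.max_attempts,
        seed=int(np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] % 2**31),
    )


def build_dataset(
    sharps: list[SliceImage],
    family: KernelFamily,
    config: PipelineConfig,
) -> list[TrainingPair]:
    """Morph each sharp slice, blur each morph, align, tag and split.

    Per sharp slice: draw ``n_morphs`` radial-stretch variants, blur each
    with a kernel drawn uniformly from the family, register the blurred
    image back onto its sharp variant (alignment failures are flagged on
    the pair, not fatal), then assign train/validation splits at the
    configured ratio.  Deterministic for a fixed global seed.
    """
    if len(family) == 0:
        raise ValueError("kernel family is empty")
    if not sharps:
        raise ValueError("no sharp slices given")
    rng = np.random.default_rng([config.seed, 2])
    mc, rc = config.morph, config.registration
    pairs: list[TrainingPair] = []
    for sharp in sharps:
        variants, specs = augment(
            sharp,
            n_morphs=mc.n_morphs,
            rng=rng,
            stretches_per_variant=mc.stretches_per_variant,
            radius_range=mc.radius_range,
            margin=mc.margin,
            epsilon=mc.epsilon,
            return_specs=True,
        )
        for variant, vspecs in zip(variants, specs):
            ki = int(rng.integers(len(family)))
            kernel = family[ki]
            blurred = degrade(variant, kernel, config=config.degradation, rng=rng)
            pair = align_pair(
                blurred,
                variant,
                kind=rc.kind,
                n_keypoints=rc.n_keypoints,
                inlier_threshold=rc.inlier_threshold,
            )
            pair.kernel_id = kernel.kernel_id
            pair.plane = sharp.plane
            pair.provenance = {
                "source_id": sharp.id,
                "variant_id": variant.id,
                "morphs": [
                    {"center": list(s.center), "radius": s.radius, "epsilon": s.epsilon} for s in vspecs
                ],
            }
            pairs.append(pair)
    # 4:1 train/validation assignment over a seeded shuffle
    tr, va = config.training.split
    order = rng.permutation(len(pairs))
    n_train = int(round(len(pairs) * tr / (tr + va)))
    for rank, i in enumerate(order):
        pairs[i].split = "train" if rank < n_train else "validation"
    return pairs


def dataset_manifest(pairs: list[TrainingPair]) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(pairs):
        rows.append(
            {
                "pair_id": f"pair-{i:05d}",
                "source_id": p.provenance.get("source_id", ""),
                "variant_id": p.provenance.get("variant_id", ""),
                "plane": p.plane,
                "kernel_id": p.kernel_id,
                "d_row": p.transform.shift[0],
                "d_col": p.transform.shift[1],
                "status": p.status,
                "split": p.split,
                "morphs": repr(p.provenance.get("morphs", [])),
            }
        )
    return pd.DataFrame(rows)


def evaluate_run(
    checkpoint: Checkpoint,
    pairs: list[TrainingPair] | None = None,
    images: list[SliceImage] | None = None,
    config: MetricsConfig | None = None,
    compute_piqe: bool = False,
) -> QualityReport:
    """Score a checkpoint on paired data (RMSE/PSNR, binned by degradation
    level) or on unpaired degraded images (PIQE only).

    Model outputs are histogram-matched to the original image before any
    metric is computed: in paired mode the original is the sharp target,
    in unpaired mode (real scans without ground truth) the degraded
    input is the only available anchor.
    """
    from .register import histogram_match

    config = config or MetricsConfig()
    hm = config.histogram_match_outputs
    rows = []
    if pairs:
        for i, p in enumerate(pairs):
            corr = correct(checkpoint, p.degraded)
            if hm:
                corr = histogram_match(corr, p.target)
            row = {
                "image_id": p.provenance.get("variant_id", f"pair-{i:05d}"),
                "plane": p.plane,
                "rmse_degraded": rmse(p.degraded, p.target),
                "rmse_corrected": rmse(corr, p.target),
                "psnr_degraded": psnr(p.degraded, p.target),
                "psnr_corrected": psnr(corr, p.target),
            }
            if compute_piqe:
                row["piqe_degraded"] = piqe(p.degraded)
                row["piqe_corrected"] = piqe(corr)
            rows.append(row)
    elif images:
        for img in images:
            corr = correct(checkpoint, img, histogram_match_to_input=hm)
            rows.append(
                {
                    "image_id": img.id,
                    "plane": img.plane,
                    "piqe_degraded": piqe(img),
                    "piqe_corrected": piqe(corr),
                }
            )
    else:
        raise ValueError("evaluate_run needs pairs or images")
    return build_report(rows, reduction_mode=config.reduction_mode)


def io_read_slices(path, format: str = "png", plane: str = "axial", slab=None) -> list[SliceImage]:
    """Read slices from PNG files or a NIfTI volume, unit-range normalized.

    For NIfTI the volume is sliced along the plane's axis (sagittal=0,
    coronal=1, axial=2 in the file's array order); ``slab`` selects the
    middle ``n`` slices (int) or an explicit ``(start, stop)`` range.
    """
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {PLANES}, got {plane!r}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file or directory: {p}")
    if format == "png":
        files = sorted(p.glob("*.png")) if p.is_dir() else [p]
        out = []
        for f in files:
            arr = np.asarray(Image.open(f).convert("L"), dtype=np.float64) / 255.0
            out.append(SliceImage(arr, plane=plane, id=f.stem))
        return out
    if format == "nifti":
        import nibabel as nib

        vol = np.asarray(nib.load(str(p)).dataobj, dtype=np.float64)
        if vol.ndim != 3:
            raise OSError(f"{p}: expected a 3-D volume, got shape {vol.shape}")
        axis = {"sagittal": 0, "coronal": 1, "axial": 2}[plane]
        n = vol.shape[axis]
        if slab is None:
            lo, hi = 0, n
        elif isinstance(slab, int):
            lo = max(0, (n - slab) // 2)
            hi = min(n, lo + slab)
        else:
            lo, hi = slab
        peak = vol.max()
        vol = vol / peak if peak > 0 else vol
        out = []
        for i in range(lo, hi):
            sl = np.take(vol, i, axis=axis)
            out.append(SliceImage(np.clip(sl, 0.0, 1.0), plane=plane, id=f"{p.stem}-{plane}-{i:04d}"))
        return out
    raise ValueError(f"unknown format {format!r}")


def write_pairs(pairs: list[TrainingPair], out_dir) -> pd.DataFrame:
    """Write degraded/target PNGs plus the provenance manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dataset_manifest(pairs)
    for row, p in zip(manifest.itertuples(), pairs):
        for tag, img in (("degraded", p.degraded), ("target", p.target)):
            arr = np.round(img.pixels * 255.0).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out / f"{row.pair_id}.{tag}.png")
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_pairs(in_dir) -> list[TrainingPair]:
    """Reload pairs written by :func:`write_pairs` (metrics-grade fidelity)."""
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv", keep_default_na=False)
    pairs = []
    for row in manifest.itertuples():
        imgs = {}
        for tag in ("degraded", "target"):
            arr = np.asarray(Image.open(src / f"{row.pair_id}.{tag}.png"), dtype=np.float64) / 255.0
            imgs[tag] = SliceImage(arr, plane=row.plane, id=f"{row.pair_id}-{tag}")
        pairs.append(
            TrainingPair(
                degraded=imgs["degraded"],
                target=imgs["target"],
                kernel_id=row.kernel_id,
                plane=row.plane,
                split=row.split,
                status=row.status,
                provenance={"variant_id": row.variant_id, "source_id": row.source_id},
            )
        )
    return pairs
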