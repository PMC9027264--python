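import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from mrimotion import SliceImage, bin_by_psnr, build_report, psnr, rmse
from mrimotion.metrics import PSNR_LEVELS, psnr_level
from mrimotion.piqe import piqe


class TestRmse:
    def test_identical_is_zero(self, phantom_small):
        assert rmse(phantom_small, phantom_small) == 0.0

    def test_opposite_constants(self):
        a = SliceImage(np.zeros((16, 16)))
        b = SliceImage(np.ones((16, 16)))
        assert rmse(a, b) == 1.0

    def test_matches_brute_force(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        b = rng.uniform(0, 1, (16, 16))
        acc = 0.0
        for i in range(16):
            for j in range(16):
                acc += (a[i, j] - b[i, j]) ** 2
        assert rmse(a, b) == pytest.approx(math.sqrt(acc / 256), abs=1e-12)

    def test_eight_bit_scale_convention(self, rng):
        a, b = rng.uniform(0, 1, (8, 8)), rng.uniform(0, 1, (8, 8))
        assert rmse(a, b, scale=255.0) == pytest.approx(rmse(a, b) * 255.0, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.zeros((4, 4)), np.zeros((5, 5)))


class TestPsnr:
    def test_identical_infinite(self, phantom_small):
        assert psnr(phantom_small, phantom_small) == math.inf

    def test_unit_rmse_gives_zero_db(self):
        assert psnr(np.zeros((8, 8)), np.ones((8, 8))) == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_duality_with_rmse(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0, 1, (12, 12)), rng.uniform(0, 1, (12, 12))
        r = rmse(a, b)
        assert psnr(a, b) == pytest.approx(-20.0 * math.log10(r), abs=1e-9)

    def test_peak_scaling_consistency(self, rng):
        a, b = rng.uniform(0, 1, (8, 8)), rng.uniform(0, 1, (8, 8))
        assert psnr(a * 1.0, b * 1.0, peak=1.0) == pytest.approx(psnr(255 * a, 255 * b, peak=255.0), abs=1e-9)

    def test_bad_peak_rejected(self, rng):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((4, 4)), peak=0.0)


class TestBinning:
    @pytest.mark.parametrize(
        "value,label",
        [(16.2, "<17"), (17.0, "[17, 18)"), (17.999, "[17, 18)"), (18.0, "[18, 19)"), (19.5, "[19, 20)"), (20.0, ">20"), (25.0, ">20"), (math.inf, ">20")],
    )
    def test_level_labels(self, value, label):
        assert psnr_level(value) == label

    def test_every_pair_assigned_once(self, rng):
        pairs = []
        for _ in range(40):
            a = rng.uniform(0, 1, (16, 16))
            pairs.append((a + rng.normal(0, rng.uniform(0.01, 0.2), a.shape), a))
        groups = bin_by_psnr(pairs)
        assert set(groups) == set(PSNR_LEVELS)
        all_idx = sorted(i for idxs in groups.values() for i in idxs)
        assert all_idx == list(range(40))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bin_by_psnr([])


class TestBuildReport:
    def test_single_image_reduction(self):
        rows = [{"image_id": "a", "rmse_degraded": 0.2, "rmse_corrected": 0.1}]
        rep = build_report(rows)
        assert rep.per_bin.iloc[0]["rmse_reduction_pct"] == pytest.approx(50.0)

    def test_single_image_gain(self):
        rows = [{"image_id": "a", "psnr_degraded": 15.0, "psnr_corrected": 18.0}]
        rep = build_report(rows)
        assert rep.per_bin.iloc[0]["gain_db"] == pytest.approx(3.0)

    def test_piqe_reduction_mirrors_table_arithmetic(self):
        # two images whose mean degraded/corrected PIQE are 12.45 -> 6.86
        rows = [
            {"image_id": "a", "piqe_degraded": 10.0, "piqe_corrected": 5.51},
            {"image_id": "b", "piqe_degraded": 14.9, "piqe_corrected": 8.21},
        ]
        rep = build_report(rows, reduction_mode="ratio_of_means")
        red = rep.per_bin.iloc[0]["piqe_reduction_pct"]
        assert red == pytest.approx((12.45 - 6.86) / 12.45 * 100.0, abs=1e-9)

    def test_mean_of_ratios_vs_ratio_of_means(self):
        rows = [
            {"image_id": "a", "rmse_degraded": 0.2, "rmse_corrected": 0.05},
            {"image_id": "b", "rmse_degraded": 0.1, "rmse_corrected": 0.09},
        ]
        mor = build_report(rows, reduction_mode="mean_of_ratios").per_bin.iloc[0]["rmse_reduction_pct"]
        rom = build_report(rows, reduction_mode="ratio_of_means").per_bin.iloc[0]["rmse_reduction_pct"]
        assert mor == pytest.approx((75.0 + 10.0) / 2)
        assert rom == pytest.approx((0.3 - 0.14) / 0.3 * 100)

    def test_infinite_psnr_capped_in_aggregates(self):
        rows = [{"image_id": "a", "psnr_degraded": 20.0, "psnr_corrected": math.inf}]
        rep = build_report(rows)
        assert rep.per_bin.iloc[0]["psnr_corrected_mean"] == pytest.approx(99.0)

    def test_levels_bin_rows(self, rng):
        rows = []
        for i, p in enumerate([15.0, 17.5, 18.5, 19.5, 25.0, 16.0]):
            rows.append({"image_id": str(i), "psnr_degraded": p, "psnr_corrected": p + 1, "rmse_degraded": 0.1, "rmse_corrected": 0.08})
        rep = build_report(rows)
        assert list(rep.per_bin["level"]) == list(PSNR_LEVELS)
        assert rep.per_bin.set_index("level").loc["<17", "n"] == 2

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError):
            build_report([])


# Frozen regression values for the PIQE implementation on a constructed
# 20-image suite (uniform fields, ramps, noise, blocky patterns, phantom
# variants).  They pin the scorer's behavior; the closed-form anchors are
# the uniform/ramp rows, which have no spatially active blocks and score
# exactly (0 + C)/(C + 0) * 100 = 100 by the pooling formula.
PIQE_SUITE = [
    ("uniform_mid", 100.0),
    ("uniform_dark", 100.0),
    ("uniform_bright", 100.0),
    ("hramp", 100.0),
    ("vramp", 100.0),
    ("diag_ramp", 100.0),
    ("gauss_noise", 76.1568576142),
    ("salt_pepper", 74.8210155286),
    ("checker2", 98.8887928257),
    ("blocks8", 83.0065290775),
    ("blocks16", 92.2423374527),
    ("phantom_sharp", 90.2757033302),
    ("phantom_blur", 94.4704955824),
    ("phantom_noisy", 65.0308309450),
    ("phantom_smooth", 100.0),
    ("sine_low", 100.0),
    ("sine_high", 100.0),
    ("edge_step", 100.0),
    ("texture", 12.3692772829),
    ("phantom_sagittal", 90.8936294529),
]


def _piqe_suite_images() -> dict[str, np.ndarray]:
    import mrimotion as mm
    from mrimotion.kernels import recenter_kernel

    rng = np.random.default_rng(2024)
    s: dict[str, np.ndarray] = {}
    s["uniform_mid"] = np.full((64, 64), 0.5)
    s["uniform_dark"] = np.zeros((64, 64))
    s["uniform_bright"] = np.ones((64, 64))
    s["hramp"] = np.tile(np.linspace(0, 1, 64), (64, 1))
    s["vramp"] = s["hramp"].T
    s["diag_ramp"] = (s["hramp"] + s["vramp"]) / 2
    s["gauss_noise"] = np.clip(0.5 + 0.15 * rng.standard_normal((64, 64)), 0, 1)
    s["salt_pepper"] = np.where(rng.random((64, 64)) < 0.05, rng.integers(0, 2, (64, 64)).astype(float), 0.5)
    s["checker2"] = np.indices((64, 64)).sum(0) % 2 * 1.0
    s["blocks8"] = np.kron(rng.random((8, 8)), np.ones((8, 8)))
    s["blocks16"] = np.kron(rng.random((4, 4)), np.ones((16, 16)))
    s["phantom_sharp"] = mm.make_phantom(1, "axial", 64).pixels
    s["phantom_blur"] = mm.degrade(
        mm.make_phantom(1, "axial", 64), recenter_kernel(mm.generate_family(1, 9, 9, seed=3)[0])
    ).pixels
    s["phantom_noisy"] = np.clip(s["phantom_sharp"] + 0.1 * rng.standard_normal((64, 64)), 0, 1)
    s["phantom_smooth"] = ndi.gaussian_filter(s["phantom_sharp"], 2.0)
    s["sine_low"] = 0.5 + 0.4 * np.sin(2 * np.pi * np.arange(64) / 32)[None, :] * np.ones((64, 1))
    s["sine_high"] = 0.5 + 0.4 * np.sin(2 * np.pi * np.arange(64) / 4)[None, :] * np.ones((64, 1))
    s["edge_step"] = np.where(np.arange(64)[None, :] < 32, 0.2, 0.8) * np.ones((64, 1))
    s["texture"] = ndi.gaussian_filter(rng.random((64, 64)), 1.0)
    s["phantom_sagittal"] = mm.make_phantom(2, "sagittal", 64).pixels
    return s


class TestPiqe:
    def test_scores_in_range(self):
        for name, img in _piqe_suite_images().items():
            v = piqe(np.clip(img, 0, 1))
            assert 0.0 <= v <= 100.0, name

    def test_uniform_field_scores_exactly_100(self):
        # no active blocks: pooled score is (0 + 1)/(1 + 0) * 100
        assert piqe(np.full((64, 64), 0.3)) == 100.0

    def test_frozen_suite_regression(self):
        imgs = _piqe_suite_images()
        for name, expected in PIQE_SUITE:
            assert piqe(np.clip(imgs[name], 0, 1)) == pytest.approx(expected, abs=1e-3), name

    def test_noise_raises_score_on_textured_base(self):
        rng = np.random.default_rng(2024)
        tex = ndi.gaussian_filter(rng.random((64, 64)), 1.0)
        noisy = np.where(rng.random((64, 64)) < 0.08, rng.integers(0, 2, (64, 64)).astype(float), tex)
        assert piqe(np.clip(noisy, 0, 1)) > piqe(tex)

    def test_blur_monotone_in_kernel_length(self):
        import mrimotion as mm
        from mrimotion.kernels import recenter_kernel

        means = []
        for length in (1, 5, 10, 15):
            fam = mm.generate_family(10, length, length, seed=50 + length)
            rng = np.random.default_rng(0)
            vals = []
            for s in range(12):
                ph = mm.make_phantom(s, ("sagittal", "axial", "coronal")[s % 3], 64)
                k = recenter_kernel(fam[int(rng.integers(len(fam)))])
                vals.append(piqe(mm.degrade(ph, k)))
            means.append(np.mean(vals))
        assert all(means[i] <= means[i + 1] + 1e-9 for i in range(len(means) - 1))

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            piqe(np.zeros((8, 8)))
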