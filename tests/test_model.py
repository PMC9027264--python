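import math

import numpy as np
import pytest

from mrimotion.model import (
    Checkpoint,
    DiscriminatorSpec,
    FeatureExtractor,
    GeneratorSpec,
    LossSpec,
    TrainConfig,
    TrainingFault,
    build_discriminator,
    build_generator,
    correct,
    split_pairs,
    total_loss,
    train,
)
from mrimotion.phantom import SliceImage, make_phantom
from mrimotion.protocols import (
    make_supervised_pairs,
    smoke_discriminator_spec,
    smoke_generator_spec,
    smoke_train_config,
)

from .oracles import generator_param_count

SMALL_GEN = GeneratorSpec(base_filters=4, n_residual_blocks=2, n_encode_blocks=3, n_decode_blocks=2)


class TestGenerator:
    @pytest.mark.parametrize("size", [64, 128])
    def test_shape_preserved(self, size):
        g = build_generator(SMALL_GEN, seed=0)
        x = np.random.default_rng(0).uniform(0, 1, (1, 1, size, size))
        assert g.forward(x).shape == x.shape

    def test_zeroed_residual_branch_is_identity(self):
        g = build_generator(SMALL_GEN, seed=0)
        for p in g.params():
            p.value[...] = 0.0
        x = np.random.default_rng(1).uniform(0, 1, (2, 1, 64, 64))
        assert np.array_equal(g.forward(x), x)

    def test_fresh_model_is_identity_by_zero_head(self):
        # the head conv is zero-initialized, so an untrained model passes
        # its input through unchanged
        g = build_generator(SMALL_GEN, seed=3)
        x = np.random.default_rng(2).uniform(0, 1, (1, 1, 64, 64))
        assert np.abs(g.forward(x) - x).max() == 0.0

    def test_incompatible_size_names_dimension(self):
        g = build_generator(SMALL_GEN, seed=0)
        with pytest.raises(ValueError, match="height 30"):
            g.forward(np.zeros((1, 1, 30, 32)))

    def test_parameter_count_matches_closed_form(self):
        spec = GeneratorSpec(base_filters=8, n_residual_blocks=4)
        g = build_generator(spec, seed=0)
        expected = generator_param_count(8, 5, 4, 4, 7, 3)
        assert sum(p.value.size for p in g.params()) == expected

    def test_mismatched_encode_decode_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(n_encode_blocks=5, n_decode_blocks=3).validate()


class TestDiscriminator:
    def test_output_is_probability(self):
        d = build_discriminator(smoke_discriminator_spec(), seed=0)
        x = np.random.default_rng(0).uniform(0, 1, (3, 1, 64, 64))
        p = d.forward(x)
        assert p.shape == (3,)
        assert np.all((p > 0) & (p < 1))

    def test_default_filter_widths_rise_64_to_512(self):
        spec = DiscriminatorSpec()
        f = spec.filters
        assert f[0] == 64 and max(f) == 512 and len(f) == 7
        assert all(a <= b for a, b in zip(f, f[1:]))

    def test_eval_mode_deterministic(self):
        d = build_discriminator(smoke_discriminator_spec(), seed=1)
        x = np.random.default_rng(1).uniform(0, 1, (2, 1, 64, 64))
        assert np.array_equal(d.forward(x, training=False), d.forward(x, training=False))

    def test_classification_threshold(self):
        d = build_discriminator(smoke_discriminator_spec(), seed=0)
        x = np.random.default_rng(0).uniform(0, 1, (2, 1, 64, 64))
        assert np.array_equal(d.classify(x), d.forward(x) >= 0.5)


class TestTotalLoss:
    def test_identical_images_leave_only_adversarial_term(self, rng):
        img = rng.uniform(0, 1, (2, 1, 32, 32))
        comps = total_loss(img, img.copy(), d_real=np.array([0.8]), d_fake=np.array([0.3]), features=FeatureExtractor(seed=0))
        assert comps.l_x == 0.0 and comps.l_mse == 0.0
        assert comps.total == pytest.approx(comps.l_gan)
        assert comps.l_gan == pytest.approx(math.log(0.8) + math.log(0.7))

    def test_hand_computed_mse(self):
        gen = np.zeros((1, 1, 2, 2))
        tgt = np.ones((1, 1, 2, 2))
        comps = total_loss(gen, tgt, d_real=np.array([0.5]), d_fake=np.array([0.5]))
        assert comps.l_mse == pytest.approx(1.0)

    def test_decomposition_exact_at_default_weights(self, rng):
        gen = rng.uniform(0, 1, (1, 1, 32, 32))
        tgt = rng.uniform(0, 1, (1, 1, 32, 32))
        comps = total_loss(gen, tgt, np.array([0.6]), np.array([0.4]), features=FeatureExtractor(seed=1))
        assert comps.total - (comps.l_gan + 100.0 * comps.l_x + 50.0 * comps.l_mse) == pytest.approx(0.0, abs=1e-9)

    def test_extreme_probabilities_clamped_finite(self):
        comps = total_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 4, 4)), np.array([1.0]), np.array([1.0]))
        assert math.isfinite(comps.total)

    def test_nan_raises_training_fault(self):
        bad = np.full((1, 1, 4, 4), np.nan)
        with pytest.raises(TrainingFault):
            total_loss(bad, np.zeros((1, 1, 4, 4)), np.array([0.5]), np.array([0.5]))


class TestTrain:
    def test_split_ratio_4_to_1(self):
        pairs = make_supervised_pairs(1, n_per_plane=2, size=64)  # placeholder pair objects
        idx_tr, idx_va = split_pairs(list(range(100)), (4, 1), np.random.default_rng(0))
        assert len(idx_tr) == 80 and len(idx_va) == 20
        assert sorted(idx_tr + idx_va) == list(range(100))

    def test_same_seed_identical_history(self):
        pairs = make_supervised_pairs(3, n_per_plane=2)
        cfg = smoke_train_config(seed=3, max_steps=4)
        _, h1 = train(pairs, config=cfg, gen_spec=smoke_generator_spec(), disc_spec=smoke_discriminator_spec())
        _, h2 = train(pairs, config=cfg, gen_spec=smoke_generator_spec(), disc_spec=smoke_discriminator_spec())
        assert h1.equals(h2)

    def test_history_columns_and_loss_identity(self):
        pairs = make_supervised_pairs(4, n_per_plane=2)
        ck, hist = train(
            pairs, config=smoke_train_config(seed=4, max_steps=3), gen_spec=smoke_generator_spec(), disc_spec=smoke_discriminator_spec()
        )
        for col in ("d_loss", "l_gan", "g_adv", "l_x", "l_mse", "g_total", "val_mse"):
            assert col in hist
        recomputed = hist.g_adv + 100.0 * hist.l_x + 50.0 * hist.l_mse
        assert np.allclose(hist.g_total, recomputed, atol=1e-9)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], config=smoke_train_config(0))

    def test_plane_tag_carried_into_checkpoint(self):
        pairs = make_supervised_pairs(5, n_per_plane=2)
        cfg = smoke_train_config(seed=5, max_steps=2)
        cfg.plane = "coronal"
        ck, _ = train(pairs, config=cfg, gen_spec=smoke_generator_spec(), disc_spec=smoke_discriminator_spec())
        assert ck.plane == "coronal"


class TestCheckpointAndCorrect:
    def test_zero_residual_checkpoint_identity(self, phantom_small):
        g = build_generator(SMALL_GEN, seed=0)
        ck = Checkpoint.from_generator(g, seed=0)
        out = correct(ck, phantom_small)
        assert np.array_equal(out.pixels, phantom_small.pixels)

    def test_histogram_match_contract(self, phantom_small):
        g = build_generator(SMALL_GEN, seed=2)
        # give the head nonzero weights so the output differs from the input
        g.body.layers[-2].w.value[...] = np.random.default_rng(0).normal(0, 0.05, g.body.layers[-2].w.value.shape)
        ck = Checkpoint.from_generator(g, seed=2)
        out = correct(ck, phantom_small, histogram_match_to_input=True)
        # quantile functions agree up to interpolation at tied plateaus
        dev = np.abs(np.sort(out.pixels.ravel()) - np.sort(phantom_small.pixels.ravel()))
        assert dev.max() < 0.01 and np.percentile(dev, 99) < 1e-3

    def test_size_mismatch_rejected(self):
        g = build_generator(SMALL_GEN, seed=0)
        ck = Checkpoint.from_generator(g, seed=0)
        with pytest.raises(ValueError):
            correct(ck, SliceImage(np.zeros((30, 30))))

    def test_save_load_roundtrip(self, tmp_path, phantom_small):
        pairs = make_supervised_pairs(6, n_per_plane=2)
        ck, _ = train(
            pairs, config=smoke_train_config(seed=6, max_steps=2), gen_spec=smoke_generator_spec(), disc_spec=smoke_discriminator_spec()
        )
        ck.save(tmp_path / "model")
        back = Checkpoint.load(tmp_path / "model")
        assert back.gen_spec == ck.gen_spec and back.plane == ck.plane
        a = correct(ck, phantom_small)
        b = correct(back, phantom_small)
        assert np.array_equal(a.pixels, b.pixels)


def test_smoke_learning_majority_of_three_seeds():
    """Validation pixel MSE after 50 steps falls below its starting value
    (checked across three seeds; the majority must improve)."""
    improved = 0
    for seed in (11, 1, 5):
        pairs = make_supervised_pairs(seed)
        _, hist = train(
            pairs, config=smoke_train_config(seed), gen_spec=smoke_generator_spec(), disc_spec=smoke_discriminator_spec()
        )
        improved += hist.val_mse.iloc[-1] < hist.val_mse.iloc[0]
    assert improved >= 2
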