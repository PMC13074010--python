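"""Preprocessing, tokenization, masking and the transformer encoder."""

import numpy as np
import pytest

from ceqea.encoder import (
    VIT16B,
    EncoderConfig,
    EncoderParams,
    PreprocessConfig,
    TinyViTClassifier,
    apply_mask,
    augment,
    build_sequence,
    classify,
    cross_entropy,
    elastic_deform,
    encoder_forward,
    patchify,
    preprocess,
    sinusoidal_positions,
    unpatchify,
)
from ceqea.quantum import BinaryMask
from ceqea.synth import SynthConfig, generate_client_dataset


class TestPreprocess:
    def test_output_shape_and_mean_centering(self):
        img = np.zeros((100, 180, 3))
        img[:] = PreprocessConfig().mean
        out = preprocess(img)
        assert out.shape == (224, 224, 3)
        # non-padded central band normalizes to exactly zero
        assert abs(out[112, 112]).max() < 1e-6

    def test_aspect_ratio_preserved_with_zero_bands(self):
        cfg = PreprocessConfig()
        img = np.ones((100, 200, 3)) * 0.5
        out = preprocess(img, cfg)
        # 1:2 content scaled to 112x224, vertical zero bands of 56 rows
        pad_value = (0.0 - np.asarray(cfg.mean)) / np.asarray(cfg.std)
        np.testing.assert_allclose(out[:56], np.broadcast_to(pad_value, (56, 224, 3)), atol=1e-6)
        np.testing.assert_allclose(out[-56:], np.broadcast_to(pad_value, (56, 224, 3)), atol=1e-6)
        assert np.abs(out[112] - (0.5 - np.asarray(cfg.mean)) / np.asarray(cfg.std)).max() < 1e-6

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((10, 10)))

    def test_divisibility_enforced(self):
        with pytest.raises(ValueError):
            PreprocessConfig(target_size=225, patch_size=16)


class TestAugment:
    def test_identity_when_disabled(self):
        cfg = PreprocessConfig(
            brightness=0, contrast=0, saturation=0, blur_sigma_max=0, flip=False, rotate90=False
        )
        img = np.random.default_rng(0).random((16, 16, 3))
        np.testing.assert_allclose(augment(img, cfg, np.random.default_rng(1)), img)

    def test_brightness_factor_bounded(self):
        cfg = PreprocessConfig(
            brightness=0.2, contrast=0, saturation=0, blur_sigma_max=0, flip=False, rotate90=False
        )
        img = np.full((8, 8, 3), 0.5)
        for s in range(20):
            out = augment(img, cfg, np.random.default_rng(s))
            assert 0.5 * 0.8 - 1e-9 <= out.mean() <= 0.5 * 1.2 + 1e-9

    def test_reproducible_from_seed(self):
        cfg = PreprocessConfig()
        img = np.random.default_rng(3).random((16, 16, 3))
        a = augment(img, cfg, np.random.default_rng(9))
        b = augment(img, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_elastic_stub_warns_and_is_identity(self):
        img = np.random.default_rng(0).random((8, 8, 3))
        with pytest.warns(UserWarning):
            out = elastic_deform(img)
        np.testing.assert_array_equal(out, img)


class TestPatchify:
    @pytest.mark.parametrize(
        "side, p, n_patches, length",
        [(224, 16, 196, 768), (32, 8, 16, 192)],
    )
    def test_patch_counts_and_lengths(self, side, p, n_patches, length):
        img = np.random.default_rng(0).random((side, side, 3))
        patches = patchify(img, p)
        assert patches.shape == (n_patches, length)

    def test_partition_property(self):
        img = np.random.default_rng(1).random((32, 32, 3))
        np.testing.assert_array_equal(unpatchify(patchify(img, 8), 32, 8), img)

    def test_non_divisible_side_rejected(self):
        with pytest.raises(ValueError):
            patchify(np.zeros((30, 30, 3)), 8)


class TestSequence:
    def test_sequence_shapes(self):
        cfg = EncoderConfig(d=32, n_layers=1, n_heads=4, patch_dim=192, n_tokens=17, n_classes=2)
        params = EncoderParams(cfg, seed=0)
        patches = np.random.default_rng(0).random((16, 192))
        seq = build_sequence(patches, params)
        assert seq.shape == (17, 32)

    def test_vit16b_preset_geometry(self):
        assert VIT16B.n_tokens == 197
        assert VIT16B.patch_dim == 768
        assert VIT16B.d == 768
        assert VIT16B.head_dim == 64
        assert VIT16B.ffn_dim == 3072

    def test_zero_projection_leaves_positional_rows(self):
        cfg = EncoderConfig(d=8, n_layers=1, n_heads=2, patch_dim=12, n_tokens=5, n_classes=2)
        params = EncoderParams(cfg, seed=0)
        params.params["embed_W"][:] = 0.0
        params.params["embed_b"][:] = 0.0
        params.params["cls"][:] = 0.0
        seq = build_sequence(np.zeros((4, 12)), params)
        np.testing.assert_allclose(seq[0], 0.0)
        np.testing.assert_allclose(seq[1:], sinusoidal_positions(5, 8)[1:])


class TestApplyMask:
    @pytest.fixture
    def seq(self):
        return np.random.default_rng(0).random((10, 6))

    def test_all_ones_identity_both_modes(self, seq):
        mask = BinaryMask(np.ones(10, dtype=np.int8))
        np.testing.assert_array_equal(apply_mask(seq, mask, "zero"), seq)
        np.testing.assert_array_equal(apply_mask(seq, mask, "drop"), seq)

    def test_drop_mode_keeps_rows_in_order(self, seq):
        mask = BinaryMask.from_indices(10, [0, 5, 9])
        out = apply_mask(seq, mask, "drop")
        np.testing.assert_array_equal(out, seq[[0, 5, 9]])

    def test_zero_mode_zeroes_masked_rows(self, seq):
        mask = BinaryMask.from_indices(10, [0, 2])
        out = apply_mask(seq, mask, "zero")
        np.testing.assert_array_equal(out[[0, 2]], seq[[0, 2]])
        assert np.all(out[[1, 3, 4, 5, 6, 7, 8, 9]] == 0)

    def test_class_token_must_be_retained(self, seq):
        mask = BinaryMask.from_indices(10, [1, 2])
        with pytest.raises(ValueError):
            apply_mask(seq, mask, "drop")


class TestEncoderForward:
    def small(self, **kw):
        cfg = EncoderConfig(d=8, n_layers=2, n_heads=2, patch_dim=12, n_tokens=5, n_classes=3, **kw)
        return cfg, EncoderParams(cfg, seed=1)

    def test_zero_weights_residual_passthrough(self):
        cfg, params = self.small()
        for key, val in params.params.items():
            if key.startswith(("Wq", "Wk", "Wv", "Wo", "W1", "W2", "b1", "b2")):
                val[:] = 0.0
        seq = np.random.default_rng(0).random((5, 8))
        np.testing.assert_allclose(encoder_forward(seq, params), seq, atol=1e-12)

    def test_shape_preserved_and_single_token(self):
        cfg, params = self.small()
        seq = np.random.default_rng(0).random((5, 8))
        assert encoder_forward(seq, params).shape == (5, 8)
        single = np.random.default_rng(1).random((1, 8))
        assert encoder_forward(single, params).shape == (1, 8)

    def test_classify_probabilities_and_loss(self):
        cfg, params = self.small()
        seq = np.random.default_rng(0).random((5, 8))
        probs = classify(encoder_forward(seq, params), params)
        assert probs.shape == (3,)
        assert probs.sum() == pytest.approx(1.0)
        uniform = np.full((1, 3), 1 / 3)
        assert cross_entropy(uniform, np.array([1])) == pytest.approx(np.log(3))
        onehot = np.array([[0.0, 1.0, 0.0]])
        assert cross_entropy(onehot, np.array([1])) == pytest.approx(0.0, abs=1e-9)

    def test_attention_op_counter_matches_square_law(self):
        cfg, params = self.small()
        mask = BinaryMask.from_indices(5, [0, 2, 3])
        seq = apply_mask(np.random.default_rng(0).random((5, 8)), mask, "drop")
        counter = []
        encoder_forward(seq, params, op_counter=counter)
        assert len(counter) == cfg.n_layers * cfg.n_heads
        assert all(ops == 3 * 3 for (_, _, ops) in counter)


class TestGradients:
    def test_gradients_match_finite_differences(self):
        cfg = EncoderConfig(d=8, n_layers=1, n_heads=2, patch_dim=12, n_tokens=5, n_classes=2)
        model = TinyViTClassifier(cfg, seed=0)
        rng = np.random.default_rng(0)
        patches = rng.random((3, 4, 12))
        labels = np.array([0, 1, 0])
        mask = BinaryMask.from_indices(5, [0, 1, 3, 4])
        _, grads = model.loss_and_grads(patches, labels, mask)
        eps = 1e-6
        for key in ["embed_W", "cls", "Wq_0", "Wo_0", "W1_0", "ln1_g_0", "head_W", "b2_0"]:
            arr = model.params.params[key]
            flat_idx = rng.integers(0, arr.size, size=3)
            for fi in flat_idx:
                idx = np.unravel_index(fi, arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = model.loss(patches, labels, mask)
                arr[idx] = orig - eps
                lm = model.loss(patches, labels, mask)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(fd, abs=1e-5, rel=1e-4), key

    def test_tiny_encoder_trains_on_noiseless_planted_data(self):
        # trainability smoke test: >= 90% train accuracy within 200 steps
        scfg = SynthConfig(n_classes=2, noise_sigma=0.0, n_samples=60)
        data = generate_client_dataset(scfg, np.random.default_rng(5))
        patches = np.stack([patchify(img, scfg.patch_size) for img in data.images])
        cfg = EncoderConfig(d=32, n_layers=2, n_heads=4, patch_dim=192, n_tokens=17, n_classes=2)
        model = TinyViTClassifier(cfg, seed=0)
        model.train(patches, data.labels, steps=200, lr=1e-2, seed=0)
        assert model.accuracy(patches, data.labels) >= 0.9

    def test_head_only_training_leaves_backbone_untouched(self):
        scfg = SynthConfig(n_classes=2, n_samples=30)
        data = generate_client_dataset(scfg, np.random.default_rng(2))
        patches = np.stack([patchify(img, scfg.patch_size) for img in data.images])
        cfg = EncoderConfig(patch_dim=192, n_tokens=17, n_classes=2)
        model = TinyViTClassifier(cfg, seed=0)
        before = model.get_param_vector()
        model.train(patches, data.labels, steps=10, head_only=True, seed=0)
        after = model.get_param_vector()
        for key in before:
            if key.startswith("head"):
                assert not np.allclose(before[key], after[key])
            else:
                np.testing.assert_array_equal(before[key], after[key])
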