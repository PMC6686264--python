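"""Encoding networks: architecture contracts, training progress, determinism,
the cross-network limiting cases, feature concatenation, persistence."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import desk_encoder_spec
from platfuse.encoders import (DEFAULT_ENCODER_SIZES, EncoderSpec,
                               LatentFeatures, concat_features, encode,
                               load_network, read_latent, save_network,
                               train_ae, train_cross, train_pooled,
                               write_latent)
from platfuse.io_data import ExpressionMatrix


def _norm_matrix(rng, n, g, platform="microarray", prefix="S"):
    return ExpressionMatrix([f"{prefix}{i}" for i in range(n)],
                            [f"G{j}" for j in range(g)],
                            rng.uniform(0, 1, size=(n, g)),
                            platform=platform, normalized=True)


def tiny_spec(seed=0, epochs=15, **kw):
    return EncoderSpec(input_dim=30, encoder_layer_sizes=(12, 8),
                       epochs=epochs, learning_rate=1e-3, seed=seed, **kw)


class TestEncoderSpec:
    def test_default_architecture_is_nine_layers_with_1024_bottleneck(self):
        spec = EncoderSpec(input_dim=10042)
        assert spec.layer_widths == [10042, 4096, 3072, 2048, 1024,
                                     2048, 3072, 4096, 10042]
        assert len(spec.layer_widths) == 9
        assert spec.latent_dim == 1024
        assert spec.dropout_rate == 0.2
        assert spec.batch_size == 32

    def test_scaled_keeps_mirror_structure(self):
        spec = EncoderSpec(input_dim=300).scaled(1 / 64)
        assert spec.encoder_layer_sizes == (64, 48, 32, 16)
        assert spec.layer_widths == [300, 64, 48, 32, 16, 32, 48, 64, 300]

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            EncoderSpec(input_dim=10, encoder_layer_sizes=(4, 0))


class TestTrainAE:
    def test_loss_decreases_and_latent_width(self, rng):
        x = _norm_matrix(rng, 60, 30)
        net, log = train_ae(x, tiny_spec(epochs=40))
        assert log.reconstruction[-1] < log.reconstruction[0]
        z = encode(net, x)
        assert z.blocks["ae"].shape == (60, 8)
        assert np.isfinite(z.matrix).all()

    def test_same_seed_reproduces_latent(self, rng):
        x = _norm_matrix(rng, 40, 30)
        z1 = encode(*[train_ae(x, tiny_spec(seed=5))[0]], x)
        z2 = encode(*[train_ae(x, tiny_spec(seed=5))[0]], x)
        np.testing.assert_allclose(z1.matrix, z2.matrix, atol=1e-6)

    def test_bce_demands_normalized_input(self, rng):
        raw = ExpressionMatrix(["a", "b", "c"], [f"G{j}" for j in range(30)],
                               rng.normal(size=(3, 30)) * 5, platform="microarray")
        with pytest.raises(ValueError, match="normalized"):
            train_ae(raw, tiny_spec())

    def test_mse_accepts_unnormalized_input(self, rng):
        raw = ExpressionMatrix(["a", "b", "c", "d"], [f"G{j}" for j in range(30)],
                               rng.normal(size=(4, 30)),
                               platform="microarray")
        net, log = train_ae(raw, tiny_spec(epochs=5,
                                           reconstruction_loss="mean_squared_error"))
        assert len(log.reconstruction) == 5

    def test_too_few_samples(self, rng):
        x = _norm_matrix(rng, 1, 30)
        with pytest.raises(ValueError, match="2 samples"):
            train_ae(x, tiny_spec())


class TestTrainPooled:
    def test_encoder_serves_both_platforms(self, rng):
        a = _norm_matrix(rng, 25, 30, "microarray")
        b = _norm_matrix(rng, 25, 30, "rnaseq", prefix="T")
        net, log = train_pooled(a, b, tiny_spec(epochs=10))
        za, zb = encode(net, a), encode(net, b)
        assert za.blocks["pooled"].shape == zb.blocks["pooled"].shape == (25, 8)

    def test_pooling_order_is_irrelevant_to_the_training_set(self, rng):
        # pooled training only sees the union of rows: swapping the platform
        # arguments must leave the trained map unchanged up to the row pool
        a = _norm_matrix(rng, 20, 30, "microarray")
        b = _norm_matrix(rng, 20, 30, "rnaseq", prefix="T")
        pooled_ab = np.vstack([a.values, b.values])
        pooled_ba = np.vstack([b.values, a.values])
        assert {tuple(r) for r in pooled_ab} == {tuple(r) for r in pooled_ba}

    def test_width_mismatch(self, rng):
        a = _norm_matrix(rng, 10, 30, "microarray")
        b = _norm_matrix(rng, 10, 29, "rnaseq", prefix="T")
        with pytest.raises(ValueError, match="width"):
            train_pooled(a, b, tiny_spec())


class TestTrainCross:
    def test_zero_cross_weight_equals_pooled_autoencoder(self, rng):
        a = _norm_matrix(rng, 20, 30, "microarray")
        b = ExpressionMatrix(a.sample_ids, a.gene_ids,
                             rng.uniform(0, 1, size=(20, 30)),
                             platform="rnaseq", normalized=True)
        spec = tiny_spec(seed=3, epochs=10, cross_loss_weight=0.0)
        cross_net, _ = train_cross(a, b, spec)
        pooled_net, _ = train_pooled(a, b, spec)
        za_cross = cross_net.encode_array(a.values, platform="microarray")
        za_pooled = pooled_net.encode_array(a.values)
        np.testing.assert_allclose(za_cross, za_pooled, atol=1e-6)

    def test_identical_platforms_loss_scales_with_cross_weight(self, rng):
        # when B == A the cross term duplicates reconstruction, so the
        # converged total loss is (1 + lambda) times the pooled loss on A
        a = _norm_matrix(rng, 40, 30, "microarray")
        b = ExpressionMatrix(a.sample_ids, a.gene_ids, a.values.copy(),
                             platform="rnaseq", normalized=True)
        spec = tiny_spec(seed=7, epochs=60, cross_loss_weight=1.0)
        _, log_cross = train_cross(a, b, spec)
        _, log_plain = train_pooled(a, b, spec)
        total = log_cross.total[-1]
        expected = 2.0 * log_plain.reconstruction[-1]
        assert abs(total - expected) / expected < 0.10

    def test_both_loss_components_decrease(self, rng):
        a = _norm_matrix(rng, 50, 30, "microarray")
        shift = np.clip(a.values + rng.normal(0, 0.05, size=a.values.shape), 0, 1)
        b = ExpressionMatrix(a.sample_ids, a.gene_ids, shift,
                             platform="rnaseq", normalized=True)
        _, log = train_cross(a, b, tiny_spec(epochs=40))
        assert log.reconstruction[-1] < log.reconstruction[0]
        assert log.cross[-1] < log.cross[0]

    def test_unpaired_samples_rejected(self, rng):
        a = _norm_matrix(rng, 10, 30, "microarray")
        b = _norm_matrix(rng, 10, 30, "rnaseq", prefix="T")
        with pytest.raises(ValueError, match="paired"):
            train_cross(a, b, tiny_spec())


class TestEncode:
    def test_width_mismatch(self, rng):
        x = _norm_matrix(rng, 10, 30)
        net, _ = train_ae(x, tiny_spec(epochs=2))
        other = _norm_matrix(rng, 4, 29)
        with pytest.raises(ValueError, match="width"):
            encode(net, other)

    def test_cross_requires_known_platform(self, rng):
        a = _norm_matrix(rng, 10, 30, "microarray")
        b = ExpressionMatrix(a.sample_ids, a.gene_ids,
                             rng.uniform(0, 1, (10, 30)),
                             platform="rnaseq", normalized=True)
        net, _ = train_cross(a, b, tiny_spec(epochs=2))
        stranger = ExpressionMatrix(["q1", "q2"], a.gene_ids,
                                    rng.uniform(0, 1, (2, 30)),
                                    platform="other", normalized=True)
        with pytest.raises(KeyError, match="other"):
            encode(net, stranger)

    def test_encode_is_deterministic(self, rng):
        x = _norm_matrix(rng, 10, 30)
        net, _ = train_ae(x, tiny_spec(epochs=5))
        np.testing.assert_array_equal(encode(net, x).matrix, encode(net, x).matrix)


class TestConcatFeatures:
    def test_three_default_blocks_fuse_to_3072(self):
        ids = ["s1", "s2"]
        blocks = [LatentFeatures(ids, {name: np.zeros((2, 1024))})
                  for name in ("ae", "pooled", "cross")]
        fused = concat_features(*blocks)
        assert fused.width == 3072
        assert list(fused.blocks) == ["ae", "pooled", "cross"]

    def test_two_blocks_fuse_to_2048(self):
        ids = ["s1"]
        fused = concat_features(LatentFeatures(ids, {"ae": np.zeros((1, 1024))}),
                                LatentFeatures(ids, {"pooled": np.zeros((1, 1024))}))
        assert fused.width == 2048

    def test_single_block_is_identity(self, rng):
        f = LatentFeatures(["s1", "s2"], {"ae": rng.normal(size=(2, 4))})
        fused = concat_features(f)
        np.testing.assert_array_equal(fused.matrix, f.matrix)

    def test_sample_mismatch_raises(self, rng):
        f1 = LatentFeatures(["s1"], {"ae": rng.normal(size=(1, 4))})
        f2 = LatentFeatures(["s2"], {"pooled": rng.normal(size=(1, 4))})
        with pytest.raises(ValueError, match="sample ids"):
            concat_features(f1, f2)

    def test_block_boundaries_recoverable(self, rng):
        f = concat_features(
            LatentFeatures(["s"], {"ae": rng.normal(size=(1, 3))}),
            LatentFeatures(["s"], {"cross": rng.normal(size=(1, 5))}),
        )
        slices = f.block_slices()
        assert slices["ae"] == slice(0, 3)
        assert slices["cross"] == slice(3, 8)


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path, rng):
        a = _norm_matrix(rng, 15, 30, "microarray")
        b = ExpressionMatrix(a.sample_ids, a.gene_ids,
                             rng.uniform(0, 1, (15, 30)),
                             platform="rnaseq", normalized=True)
        net, _ = train_cross(a, b, tiny_spec(epochs=4))
        save_network(net, tmp_path / "cross")
        loaded = load_network(tmp_path / "cross")
        np.testing.assert_allclose(encode(loaded, a).matrix,
                                   encode(net, a).matrix, atol=1e-12)

    def test_latent_tsv_round_trip(self, tmp_path, rng):
        f = concat_features(
            LatentFeatures(["s1", "s2"], {"ae": rng.normal(size=(2, 3))}),
            LatentFeatures(["s1", "s2"], {"pooled": rng.normal(size=(2, 2))}),
        )
        write_latent(f, tmp_path / "latent.tsv")
        back = read_latent(tmp_path / "latent.tsv")
        assert back.sample_ids == f.sample_ids
        assert list(back.blocks) == ["ae", "pooled"]
        np.testing.assert_allclose(back.matrix, f.matrix, atol=1e-9)


def test_shared_structure_recovery_on_trained_bundle(bundle, normalized_cohort):
    """The pooled and cross encoders put paired samples near each other in one
    latent space; their cross-platform second-component correlation must beat
    the per-platform autoencoders on the default synthetic cohort."""
    from platfuse.latent_analysis import pca_combined, pc2_cross_platform_r2
    from platfuse.workflow import latent_pair

    a_n, b_n, _, _ = normalized_cohort
    r2 = {}
    for source in ("ae", "pooled", "cross"):
        la, lb = latent_pair(bundle, a_n, b_n, source)
        r2[source] = pc2_cross_platform_r2(pca_combined(la, lb, "microarray", "rnaseq"))
    assert r2["pooled"] > r2["ae"]
    assert r2["cross"] > r2["ae"]
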