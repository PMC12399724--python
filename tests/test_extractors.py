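"""Extractor family: architecture resolution, forward-pass contracts,
training mechanics, encoding determinism."""

import numpy as np
import pytest

import harclust as h
from harclust import nn
from harclust.extractors import (AE_FAMILIES, FAMILIES, LatentFeatures,
                                 build_spec, classify, encode, load_extractor,
                                 save_extractor, train_autoencoder,
                                 train_supervised)


class TestBuildSpec:
    def test_tri_head_has_three_kernel_widths_5_7_11(self):
        spec = build_spec("tri_head_te", (64, 9), 3)
        assert tuple(spec.hyperparams["kernels"]) == (5, 7, 11)

    def test_lstm_ae_encoder_widths_128_64_with_mirrored_decoder(self):
        spec = build_spec("lstm_ae", (64, 9), 3)
        assert tuple(spec.hyperparams["lstm_units"]) == (128, 64)
        rng = np.random.default_rng(0)
        from harclust.extractors import _build_decoder
        dec = _build_decoder(spec, rng)
        widths = [l.H for l in dec.layers if isinstance(l, nn.LSTM)]
        assert widths == [64, 128]

    def test_mlp_ae_bottleneck_is_32(self):
        spec = build_spec("mlp_ae", (64, 9), 3)
        assert spec.latent_dim == 32

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            build_spec("transformer", (64, 9), 3)

    def test_indivisible_window_suggests_padding(self):
        with pytest.raises(ValueError, match="pad"):
            build_spec("cnn2d", (66, 9), 3)
        with pytest.raises(ValueError, match="pad"):
            build_spec("timedist_te", (65, 9), 3)

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="nonsense"):
            build_spec("mlp_ae", (64, 9), 3, nonsense=1)


class TestForwardContracts:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_batch_preserved_and_finite(self, family):
        rng = np.random.default_rng(0)
        spec = build_spec(family, (32, 9), 4)
        from harclust.extractors import _build_encoder
        enc = _build_encoder(spec, np.random.default_rng(1))
        x = rng.random((5, 32, 9))
        z = enc.forward(x, training=False)
        assert z.shape == (5, spec.latent_dim)
        assert np.isfinite(z).all()

    def test_tri_head_equal_kernels_with_tied_weights_agree(self):
        """With identical kernel widths and shared weights the three heads
        are one single-granularity extractor replicated."""
        spec = build_spec("tri_head_te", (32, 9), 3, kernels=(5, 5, 5))
        from harclust.extractors import _build_encoder
        enc = _build_encoder(spec, np.random.default_rng(0))
        heads = enc.layers[0].branches
        for b in heads[1:]:
            conv = b.layers[0]
            conv.W[...] = heads[0].layers[0].W
            conv.b[...] = heads[0].layers[0].b
        x = np.random.default_rng(1).random((3, 32, 9))
        outs = [b.forward(x, training=False) for b in heads]
        assert np.allclose(outs[0], outs[1]) and np.allclose(outs[0], outs[2])


class TestSupervisedTraining:
    def test_history_length_equals_epochs(self, small_split):
        tr, va, _ = small_split
        spec = build_spec("mlp_ae", (64, 9), 3)
        m = train_supervised(spec, tr, val=va, epochs=4, seed=0)
        assert len(m.training_history["loss"]) == 4
        assert len(m.training_history["val_accuracy"]) == 4

    def test_zero_epochs_rejected(self, small_split):
        spec = build_spec("mlp_ae", (64, 9), 3)
        with pytest.raises(ValueError):
            train_supervised(spec, small_split[0], epochs=0)

    def test_single_class_rejected(self, small_windows):
        from harclust.preprocess import WindowSet
        mask = small_windows.window_labels == 0
        ws = WindowSet(tensor=small_windows.tensor[mask],
                       window_labels=small_windows.window_labels[mask],
                       window_len=64, step=32)
        spec = build_spec("mlp_ae", (64, 9), 3)
        with pytest.raises(ValueError, match="2 classes"):
            train_supervised(spec, ws, epochs=1)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_every_family_separates_synthetic_classes(self, family,
                                                      small_split):
        """Validation accuracy > 0.9 on the separable fixture within 20
        epochs, for at least 2 of 3 seeds."""
        tr, va, _ = small_split
        spec = build_spec(family, (64, 9), 3)
        wins = 0
        for seed in (0, 1, 2):
            m = train_supervised(spec, tr, val=va, epochs=20, seed=seed)
            if m.training_history["val_accuracy"][-1] > 0.9:
                wins += 1
            if wins == 2:
                break
        assert wins >= 2


class TestAutoencoderTraining:
    def test_reconstruction_shape_round_trip(self, small_windows):
        spec = build_spec("mlp_ae", (64, 9), 1)
        m = train_autoencoder(spec, small_windows, epochs=2, seed=0)
        x = small_windows.tensor[:5]
        recon = m.decoder.forward(m.encoder.forward(x, training=False),
                                  training=False)
        assert recon.shape == x.shape

    def test_loss_non_increasing_on_moving_average(self, small_windows):
        spec = build_spec("hybrid_conv_lstm", (64, 9), 1)
        m = train_autoencoder(spec, small_windows, epochs=12, seed=0)
        loss = np.array(m.training_history["loss"])
        first, last = loss[:5].mean(), loss[-5:].mean()
        assert last <= first

    def test_near_zero_input_drives_loss_toward_zero(self):
        # sigmoid output needs strongly negative logits to emit ~0, so
        # give the optimizer enough steps to push the biases there
        X = np.full((20, 16, 4), 1e-3)
        spec = build_spec("mlp_ae", (16, 4), 1, hidden=(32,), bottleneck=4)
        m = train_autoencoder(spec, X, epochs=300, seed=0, lr=0.02)
        loss = m.training_history["loss"]
        assert loss[-1] < 1e-4
        assert loss[-1] < loss[0]

    def test_unscaled_input_rejected_for_sigmoid_output(self):
        X = np.random.default_rng(0).normal(size=(10, 16, 4)) * 5
        spec = build_spec("mlp_ae", (16, 4), 1)
        with pytest.raises(ValueError, match="[0, 1]"):
            train_autoencoder(spec, X, epochs=1)

    def test_supervised_only_family_rejected(self, small_windows):
        spec = build_spec("cnn2d", (64, 9), 3)
        with pytest.raises(ValueError, match="autoencoder"):
            train_autoencoder(spec, small_windows, epochs=1)
        assert set(AE_FAMILIES) == {"mlp_ae", "lstm_ae", "hybrid_conv_lstm"}


@pytest.fixture(scope="module")
def model(small_split):
    tr, va, _ = small_split
    spec = build_spec("hybrid_conv_lstm", (64, 9), 3)
    return train_supervised(spec, tr, val=va, epochs=15, seed=0)


class TestEncodeClassify:

    def test_latent_shape(self, model, small_windows):
        feats = encode(model, small_windows)
        assert feats.matrix.shape == (small_windows.n_windows,
                                      model.spec.latent_dim)

    def test_inference_deterministic(self, model, small_windows):
        a = encode(model, small_windows).matrix
        b = encode(model, small_windows).matrix
        assert np.array_equal(a, b)

    def test_permutation_equivariance(self, model, small_windows):
        from harclust.preprocess import WindowSet
        perm = np.random.default_rng(0).permutation(small_windows.n_windows)
        ws_p = WindowSet(tensor=small_windows.tensor[perm],
                         window_labels=small_windows.window_labels[perm],
                         window_len=64, step=32)
        a = encode(model, small_windows).matrix
        b = encode(model, ws_p).matrix
        assert np.allclose(a[perm], b)

    def test_shape_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="shape"):
            encode(model, np.zeros((3, 32, 9)))

    def test_classify_on_separable_fixture(self, model, small_split):
        _, _, te = small_split
        pred, acc = classify(model, te)
        assert pred.shape == (te.n_windows,)
        assert 0.0 <= acc <= 1.0
        assert acc > 0.9

    def test_classify_empty_rejected(self, model):
        with pytest.raises(ValueError, match="empty"):
            classify(model, np.zeros((0, 64, 9)))

    def test_save_load_round_trip(self, model, small_windows, tmp_path):
        path = tmp_path / "model.npz"
        save_extractor(model, path)
        loaded = load_extractor(path)
        a = encode(model, small_windows).matrix
        b = encode(loaded, small_windows).matrix
        assert np.allclose(a, b)


class TestSklearnEstimator:
    def test_fit_transform_predict(self, small_windows):
        est = h.SupervisedWindowExtractor(family="mlp_ae", epochs=5, seed=0)
        X, y = small_windows.tensor, small_windows.window_labels
        est.fit(X, y)
        Z = est.transform(X)
        assert Z.shape == (len(X), est.spec_.latent_dim)
        assert est.score(X, y) > 0.8

    def test_get_set_params_round_trip(self):
        est = h.SupervisedWindowExtractor(epochs=7)
        params = est.get_params()
        assert params["epochs"] == 7
        est.set_params(epochs=3)
        assert est.epochs == 3

    def test_latent_features_reject_non_finite(self):
        with pytest.raises(ValueError):
            LatentFeatures(matrix=np.array([[np.nan, 0.0]]))
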