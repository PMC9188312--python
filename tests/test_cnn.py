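"""Model wiring, training dynamics, determinism, persistence, CV."""

import numpy as np
import pytest

from phagemark import nn
from phagemark.cnn_classifier import (
    ModelConfig, build_model, crossvalidate, load_model, predict_class,
    predict_proba, save_model, train,
)
from phagemark.encoding import encode_batch


class TestConfig:
    def test_defaults_give_4way_50_filter_model(self):
        m = build_model(ModelConfig())
        assert m.params["W_out"].shape[1] == 4
        assert m.params["W_conv"].shape == (7 * 20, 50)

    def test_two_class_output(self):
        m = build_model(ModelConfig(n_classes=2), ["TerL", "others"])
        assert m.params["W_out"].shape[1] == 2

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(dropout_rate=1.5), "dropout_rate"),
            (dict(kernel_len=2000), "kernel_len"),
            (dict(n_classes=1), "n_classes"),
            (dict(learning_rate=0.0), "learning_rate"),
        ],
    )
    def test_invalid_config_names_constraint(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            ModelConfig(**kwargs)


def test_parameter_counts_match_layer_formulas():
    cfg = ModelConfig(kernel_len=7, n_filters=50, n_dense=100, n_classes=4)
    counts = build_model(cfg).parameter_counts()
    assert counts["conv"] == cfg.kernel_len * 20 * cfg.n_filters + cfg.n_filters
    assert counts["dense"] == cfg.n_filters * cfg.n_dense + cfg.n_dense
    assert counts["output"] == cfg.n_dense * cfg.n_classes + cfg.n_classes


def test_gradients_match_numerical_differentiation():
    """Backprop through conv/max-pool/dense agrees with finite differences."""
    rng = np.random.default_rng(0)
    X = rng.random((4, 15, 20)).astype(np.float32)
    y = rng.integers(0, 3, 4)
    params = {k: v.astype(np.float64)
              for k, v in nn.init_params(3, 4, 5, 3, rng).items()}
    _, cache = nn.forward(params, X, 3, want_cache=True)
    grads = nn.backward(params, cache, y)
    eps = 1e-6
    for name in nn.PARAM_NAMES:
        flat = params[name].reshape(-1)
        for i in range(0, flat.size, max(1, flat.size // 5)):
            old = flat[i]
            flat[i] = old + eps
            lp = nn.cross_entropy(nn.forward(params, X, 3), y)
            flat[i] = old - eps
            lm = nn.cross_entropy(nn.forward(params, X, 3), y)
            flat[i] = old
            assert grads[name].reshape(-1)[i] == pytest.approx(
                (lp - lm) / (2 * eps), abs=1e-6
            ), name


class TestTraining:
    def test_separable_data_reaches_full_training_accuracy(self, small_model):
        assert small_model.history[-1]["train_acc"] == 1.0

    def test_memorization_loss_decreases(self, small_bench, small_encoded):
        """Overfit sanity oracle: loss falls monotonically on a fixed 32-set."""
        X, y, _ = small_encoded
        sel = np.concatenate([np.nonzero(y == k)[0][:8] for k in range(4)])
        cfg = ModelConfig(len_w=X.shape[1], epochs=5, seed=5, batch_size=32,
                          dropout_rate=0.0, learning_rate=2e-3)
        m = build_model(cfg, small_bench["train"].category_order)
        train(m, X[sel], y[sel])
        losses = [h["train_loss"] for h in m.history]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_same_seed_identical_history(self, small_bench, small_encoded):
        X, y, _ = small_encoded
        cfg = ModelConfig(len_w=X.shape[1], epochs=1, seed=11)
        sel = np.concatenate([np.nonzero(y == k)[0][:32] for k in range(4)])
        runs = []
        for _ in range(2):
            m = build_model(cfg, small_bench["train"].category_order)
            train(m, X[sel], y[sel])
            runs.append(m.history[0]["train_loss"])
        assert runs[0] == runs[1]

    def test_missing_class_rejected(self, small_bench, small_encoded):
        X, y, _ = small_encoded
        cfg = ModelConfig(len_w=X.shape[1], epochs=1, seed=0)
        m = build_model(cfg, small_bench["train"].category_order)
        only_f1 = np.nonzero(y == 0)[0]
        with pytest.raises(ValueError, match="absent"):
            train(m, X[only_f1], y[only_f1])


class TestPredict:
    def test_probabilities_normalize(self, small_model, small_encoded):
        X, _, _ = small_encoded
        p = predict_proba(small_model, X[:64])
        assert p.shape == (64, 4)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_inputs_identical_outputs(self, small_model, small_encoded):
        X, _, _ = small_encoded
        batch = np.stack([X[0], X[0]])
        p = predict_proba(small_model, batch)
        np.testing.assert_array_equal(p[0], p[1])

    def test_all_zero_input_is_valid(self, small_model):
        p = predict_proba(small_model, np.zeros((1, small_model.config.len_w, 20)))
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_shape_mismatch_names_len_w(self, small_model):
        with pytest.raises(ValueError, match=str(small_model.config.len_w)):
            predict_proba(small_model, np.zeros((1, 33, 20)))

    def test_predict_class_argmax_and_tie_break(self):
        order = ["a", "b", "c", "others"]
        assert predict_class([0.1, 0.7, 0.1, 0.1], order) == "b"
        assert predict_class([0.25, 0.25, 0.25, 0.25], order) == "a"
        assert predict_class([0, 0, 0, 1], order) == "others"


class TestPersistence:
    def test_save_load_round_trip_bitwise(self, small_model, small_encoded, tmp_path):
        X, _, _ = small_encoded
        path = tmp_path / "m.phagemark"
        save_model(small_model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(
            predict_proba(small_model, X[:50]), predict_proba(loaded, X[:50])
        )
        assert loaded.category_order == small_model.category_order

    def test_alphabet_mismatch_rejected(self, small_model, tmp_path):
        path = tmp_path / "m.phagemark"
        save_model(small_model, path)
        with pytest.raises(ValueError, match="alphabet"):
            load_model(path, expected_alphabet="YWVTSRQPNMLKIHGFEDCA")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nope")


class TestCrossValidation:
    def test_stratified_folds_and_reproducibility(self, small_bench, small_spec):
        ds = small_bench["train"]
        sub = list(range(0, len(ds), 4))  # 65 records, keeps CV quick
        recs = [ds.records[i] for i in sub]
        labels = [ds.labels[i] for i in sub]
        X, _ = encode_batch(recs, small_spec)
        cfg = ModelConfig(len_w=small_spec.len_w, epochs=2, seed=0)
        reports1, mean1 = crossvalidate(cfg, X, labels, ds.category_order, k=5, seed=7)
        reports2, _ = crossvalidate(cfg, X, labels, ds.category_order, k=5, seed=7)
        assert len(reports1) == 5
        # same seed -> identical fold metrics
        for r1, r2 in zip(reports1, reports2):
            assert r1.table.equals(r2.table)
        n = len(labels)
        total_tp = sum(int(r.table.iloc[-1]["TP"]) for r in reports1)
        assert 0 <= total_tp <= n
        assert 0.0 <= mean1.macro["f1"] <= 1.0

    def test_k1_rejected(self, small_encoded, small_bench):
        X, y, _ = small_encoded
        with pytest.raises(ValueError, match="k >= 2"):
            crossvalidate(ModelConfig(len_w=X.shape[1]), X,
                          small_bench["train"].labels,
                          small_bench["train"].category_order, k=1)

    def test_class_smaller_than_k_rejected(self, small_spec):
        from phagemark.sequence_io import ProteinRecord

        recs = [ProteinRecord(f"r{i}", "ACDEFGHIK") for i in range(8)]
        X, _ = encode_batch(recs, small_spec)
        labels = ["a"] * 2 + ["others"] * 6
        with pytest.raises(ValueError, match="fewer than k"):
            crossvalidate(ModelConfig(len_w=small_spec.len_w, n_classes=2), X,
                          labels, ["a", "others"], k=5)
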