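import numpy as np
import pytest

from ctra import attention_rnn as arnn
from ctra.attention_rnn import (
    EmbeddingMatrix,
    ModelConfig,
    _backward,
    _forward,
    build_model,
    class_weights,
    init_params,
    load_embeddings,
    train,
    weighted_bce,
)
from ctra.corpus import PAD_ID, build_vocab


def _tiny_config(**overrides):
    defaults = dict(vocab_size=12, n_labels=3, embedding_dim=5,
                    recurrent_units=4, max_len=9, dense_units=6,
                    dropout_rate=0.0, seed=3)
    defaults.update(overrides)
    return ModelConfig(**defaults)


def _random_ids(rng, n, max_len, vocab_size, min_real=1):
    ids = np.zeros((n, max_len), dtype=np.int64)
    for i in range(n):
        k = rng.integers(min_real, max_len + 1)
        ids[i, :k] = rng.integers(1, vocab_size, size=k)
    return ids


class TestClassWeights:
    def test_balanced_gives_one(self):
        y = np.array([[1], [1], [0], [0]])
        assert class_weights(y) == pytest.approx([1.0])

    def test_ratio(self):
        y = np.zeros((110, 1)); y[:10] = 1
        assert class_weights(y) == pytest.approx([10.0])

    def test_clipped_at_50(self):
        y = np.zeros((10010, 1)); y[:10] = 1
        assert class_weights(y) == pytest.approx([50.0])

    def test_degenerate_label_named(self):
        y = np.ones((5, 2)); y[:, 1] = [0, 1, 0, 1, 0]
        with pytest.raises(ValueError, match="label 0"):
            class_weights(y)


class TestBuildModel:
    def test_output_arity(self):
        config = _tiny_config(n_labels=5)
        model = build_model(config)
        ids = np.array([[1, 2, 3, 0, 0, 0, 0, 0, 0]])
        assert model.predict_ids(ids).shape == (1, 5)

    def test_seeded_init_identical(self):
        a = init_params(_tiny_config())
        b = init_params(_tiny_config())
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_different_seed_differs(self):
        a = init_params(_tiny_config(seed=1))
        b = init_params(_tiny_config(seed=2))
        assert any(not np.array_equal(a[k], b[k]) for k in a)

    def test_embedding_shape_mismatch_rejected(self):
        matrix = np.zeros((3, 5))
        with pytest.raises(ValueError):
            init_params(_tiny_config(), EmbeddingMatrix(matrix, coverage=1.0))

    def test_attention_sums_to_one(self):
        params = init_params(_tiny_config())
        rng = np.random.default_rng(0)
        ids = _random_ids(rng, 8, 9, 12)
        for masking in (True, False):
            fwd = _forward(params, ids, attention_masking=masking)
            np.testing.assert_allclose(fwd["att"].sum(axis=1), 1.0, atol=1e-12)

    def test_masked_attention_ignores_padding(self):
        params = init_params(_tiny_config())
        ids = np.array([[1, 2, 0, 0, 0, 0, 0, 0, 0]])
        fwd = _forward(params, ids, attention_masking=True)
        assert fwd["att"].shape[1] == 2  # trailing padding dropped entirely


class TestGradients:
    def test_numerical_gradient_check(self):
        """Analytic backprop matches central finite differences."""
        config = _tiny_config()
        params = init_params(config)
        rng = np.random.default_rng(1)
        ids = _random_ids(rng, 4, config.max_len, config.vocab_size, min_real=3)
        y = rng.integers(0, 2, size=(4, config.n_labels)).astype(float)
        w = np.array([1.0, 2.0, 0.5])

        masking = config.attention_masking
        fwd = _forward(params, ids, attention_masking=masking)
        grads = _backward(params, fwd, y, w)

        eps = 1e-6
        for name in ("w_att", "W1", "W2", "b_f", "Wh_b", "Wx_f", "E"):
            flat = params[name].reshape(-1)
            n_checks = min(flat.size, 12)
            idx = rng.choice(flat.size, size=n_checks, replace=False)
            if name == "E":
                # padding row is frozen (gradient deliberately zeroed)
                idx = [i for i in idx if i >= config.embedding_dim]
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                up = weighted_bce(
                    _forward(params, ids, attention_masking=masking)["probs"], y, w)
                flat[i] = orig - eps
                down = weighted_bce(
                    _forward(params, ids, attention_masking=masking)["probs"], y, w)
                flat[i] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[name].reshape(-1)[i]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7), name


class TestTraining:
    @pytest.fixture(scope="class")
    @staticmethod
    def learnable_data():
        # label j is on iff token (j+2) occurs: a learnable mapping
        rng = np.random.default_rng(7)
        config = _tiny_config(n_labels=2, epochs=5, batch_size=16,
                              learning_rate=0.02)
        X = _random_ids(rng, 160, config.max_len, config.vocab_size)
        y = np.stack([(X == 2).any(axis=1), (X == 3).any(axis=1)], axis=1).astype(float)
        return config, X[:128], y[:128], X[128:], y[128:]

    def test_loss_decreases(self, learnable_data):
        config, X_tr, y_tr, X_va, y_va = learnable_data
        model = build_model(config)
        train(model, X_tr, y_tr, X_va, y_va)
        losses = model.history["train_loss"]
        assert losses[-1] < losses[0]

    def test_selected_epoch_is_argmin(self, learnable_data):
        config, X_tr, y_tr, X_va, y_va = learnable_data
        model = build_model(config)
        train(model, X_tr, y_tr, X_va, y_va)
        assert model.selected_epoch == int(np.argmin(model.history["val_loss"]))

    def test_empty_training_set_rejected(self, learnable_data):
        config, X_tr, y_tr, X_va, y_va = learnable_data
        model = build_model(config)
        with pytest.raises(ValueError):
            train(model, X_tr[:0], y_tr[:0], X_va, y_va)


class TestPredict:
    def test_permutation_invariance(self):
        params_config = _tiny_config()
        model = build_model(params_config)
        rng = np.random.default_rng(5)
        ids = _random_ids(rng, 20, 9, 12)
        perm = rng.permutation(20)
        direct = model.predict_ids(ids)[perm]
        permuted = model.predict_ids(ids[perm])
        np.testing.assert_allclose(direct, permuted, atol=1e-12)

    def test_batch_size_invariance(self):
        model = build_model(_tiny_config())
        rng = np.random.default_rng(6)
        ids = _random_ids(rng, 10, 9, 12)
        np.testing.assert_allclose(
            model.predict_ids(ids, batch_size=3),
            model.predict_ids(ids, batch_size=10),
            atol=1e-12,
        )

    def test_all_padding_input_is_handled(self):
        model = build_model(_tiny_config())
        probs = model.predict_ids(np.zeros((2, 9), dtype=np.int64))
        assert probs.shape == (2, 3)
        assert np.all((probs >= 0) & (probs <= 1))
        np.testing.assert_allclose(probs[0], probs[1], atol=1e-12)


class TestAttentionTrace:
    def test_alignment_and_normalization(self):
        vocab = build_vocab(["small pleural effusion with layering fluid"])
        config = _tiny_config(vocab_size=max(vocab.values()) + 1,
                              attention_masking=True)
        model = build_model(config, vocab=vocab)
        trace = model.attention_trace("small pleural effusion")
        assert trace.tokens == ["small", "pleural", "effusion"]
        assert trace.weights.sum() == pytest.approx(1.0)  # masked softmax
        full = model.attention_weights_full("small pleural effusion")
        assert full.sum() == pytest.approx(1.0)
        assert len(full) == config.max_len

    def test_unmasked_full_weights_sum_to_one(self):
        vocab = build_vocab(["lungs are clear"])
        config = _tiny_config(vocab_size=max(vocab.values()) + 1,
                              attention_masking=False)
        model = build_model(config, vocab=vocab)
        full = model.attention_weights_full("lungs are clear")
        assert full.sum() == pytest.approx(1.0)

    def test_html_render(self):
        vocab = build_vocab(["lungs are clear"])
        model = build_model(_tiny_config(vocab_size=max(vocab.values()) + 1),
                            vocab=vocab)
        html = model.attention_trace("lungs are clear").to_html(["a", "b", "c"])
        assert "lungs" in html and "span" in html


class TestLoadEmbeddings:
    def _write_w2v(self, path, vectors, dim, header=True):
        with open(path, "w") as fh:
            if header:
                fh.write(f"{len(vectors)} {dim}\n")
            for tok, vec in vectors.items():
                fh.write(tok + " " + " ".join(str(v) for v in vec) + "\n")

    def test_full_coverage(self, tmp_path):
        vocab = {"<pad>": 0, "<oov>": 1, "lungs": 2, "clear": 3}
        path = tmp_path / "vecs.txt"
        self._write_w2v(path, {t: [float(i)] * 4 for i, t in
                               enumerate(vocab)}, 4)
        emb = load_embeddings(path, vocab, embedding_dim=4)
        assert emb.coverage == 1.0
        np.testing.assert_allclose(emb.matrix[2], [2.0] * 4)
        np.testing.assert_allclose(emb.matrix[PAD_ID], 0.0)

    def test_zero_coverage_warns(self, tmp_path):
        vocab = {"<pad>": 0, "xyz": 1}
        path = tmp_path / "vecs.txt"
        self._write_w2v(path, {"other": [1.0, 2.0]}, 2)
        with pytest.warns(UserWarning):
            emb = load_embeddings(path, vocab, embedding_dim=2)
        assert emb.coverage == 0.0

    def test_dimension_mismatch_rejected(self, tmp_path):
        path = tmp_path / "vecs.txt"
        self._write_w2v(path, {"a": [1.0, 2.0, 3.0]}, 3)
        with pytest.raises(ValueError):
            load_embeddings(path, {"a": 1}, embedding_dim=5)

    def test_headerless_file_accepted(self, tmp_path):
        path = tmp_path / "vecs.txt"
        self._write_w2v(path, {"a": [1.0, 2.0]}, 2, header=False)
        emb = load_embeddings(path, {"<pad>": 0, "a": 1}, embedding_dim=2)
        np.testing.assert_allclose(emb.matrix[1], [1.0, 2.0])

    def test_oov_rows_seeded(self, tmp_path):
        vocab = {"<pad>": 0, "known": 1, "unknown": 2}
        path = tmp_path / "vecs.txt"
        self._write_w2v(path, {"known": [1.0, 2.0]}, 2)
        a = load_embeddings(path, vocab, embedding_dim=2, seed=4)
        b = load_embeddings(path, vocab, embedding_dim=2, seed=4)
        np.testing.assert_array_equal(a.matrix, b.matrix)
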