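"""Network construction, forward semantics, attention, and training."""

from __future__ import annotations

import numpy as np
import pytest

from affinity_attn.descriptors import DescriptorVocabulary
from affinity_attn.model import (
    Model,
    ModelConfig,
    attend,
    init_model,
    predict,
    top_attention_descriptors,
    train_model,
)
from affinity_attn.model.autograd import Tensor
from affinity_attn.model.network import _stack_dataset, encode, predict_batch
from affinity_attn.synthetic import default_signal_spec, generate_dataset


def small_config(**overrides):
    defaults = dict(u=12, encoded_dim=32, attention_dim=16, context_dim=16, seed=0)
    defaults.update(overrides)
    return ModelConfig(**defaults)


def random_input(cfg, seed=0, batch=3):
    rng = np.random.default_rng(seed)
    d = rng.poisson(2.0, size=(batch, cfg.u)).astype(float)
    v = np.abs(rng.normal(size=(batch, 6)))
    return d, v


class TestInitialization:
    def test_same_seed_gives_identical_parameters(self):
        a, b = init_model(small_config()), init_model(small_config())
        for key in a.params:
            np.testing.assert_array_equal(a.params[key].data, b.params[key].data)

    def test_embedding_is_truncated_at_two_sigma(self):
        model = init_model(small_config())
        E = model.params["E"].data
        assert np.all(np.abs(E) <= 2.0)

    def test_embedding_moments_match_truncated_normal(self):
        # mean 0, sd 0.8796 for the standard normal truncated at |z|=2
        model = init_model(ModelConfig(u=400, h=250, seed=3))
        E = model.params["E"].data.ravel()
        se = 0.8796 / np.sqrt(E.size)
        assert abs(E.mean()) < 3 * se
        assert E.std() == pytest.approx(0.8796, abs=0.01)

    def test_reference_flatten_length_is_513(self):
        assert ModelConfig(u=2500).flatten_length == 513

    def test_fusion_layer_width_is_flatten_plus_vina(self):
        cfg = small_config()
        model = init_model(cfg)
        assert model.params["enc_w"].data.shape[0] == cfg.flatten_length + 6
        bare = init_model(small_config(use_vina=False))
        assert bare.params["enc_w"].data.shape[0] == cfg.flatten_length

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(u=10, h=10, column_dense_out=2)  # too short for window 10


class TestEncode:
    def test_zero_descriptor_vector_gives_input_independent_encoding(self):
        cfg = small_config()
        model = init_model(cfg)
        vina = np.ones(6)
        e1 = encode(model, np.zeros(cfg.u), vina)
        e2 = encode(model, np.zeros(cfg.u), vina)
        assert np.array_equal(e1, e2)
        assert np.all(np.isfinite(e1))

    def test_doubling_a_count_changes_the_encoding(self):
        cfg = small_config()
        model = init_model(cfg)
        d, v = random_input(cfg, batch=1)
        d = d[0] + 1.0  # ensure nonzero
        e1 = encode(model, d, v[0])
        d2 = d.copy()
        d2[4] *= 2
        e2 = encode(model, d2, v[0])
        assert not np.allclose(e1, e2)


class TestAttention:
    def test_weights_are_normalized_and_nonnegative(self):
        cfg = small_config()
        model = init_model(cfg)
        d, v = random_input(cfg, batch=5)
        _, weights = predict_batch(model, d, v)
        assert np.all(weights >= 0)
        assert weights.sum(axis=1) == pytest.approx(np.ones(5), abs=1e-5)

    def test_identical_embedding_rows_give_uniform_weights(self):
        cfg = small_config()
        model = init_model(cfg)
        model.params["E"].data[:] = model.params["E"].data[0]
        d, v = random_input(cfg, batch=2)
        _, weights = predict_batch(model, d, v)
        assert weights == pytest.approx(np.full((2, cfg.u), 1.0 / cfg.u), abs=1e-6)

    def test_planted_collinear_key_wins_the_argmax(self):
        cfg = small_config(h=16, attention_dim=16, column_dense_out=10)
        model = init_model(cfg)
        q0 = np.full(cfg.attention_dim, 1.0)
        model.params["q_w"].data[:] = 0.0
        model.params["q_b"].data[:] = q0  # query fixed at q0 (elu is identity there)
        model.params["k_w"].data[:] = np.eye(cfg.h)
        model.params["k_b"].data[:] = 0.0
        model.params["E"].data[:] = -1.0  # keys decay to elu(-1) < 0
        model.params["E"].data[7] = 3.0 * q0  # one key collinear with the query
        out = attend(model, np.zeros(cfg.encoded_dim))
        assert int(np.argmax(out.weights)) == 7

    def test_attend_requires_attention_head(self):
        model = init_model(small_config(use_attention=False))
        with pytest.raises(ValueError):
            attend(model, np.zeros(32))


class TestPredict:
    def test_output_is_finite_and_deterministic(self):
        cfg = small_config()
        model = init_model(cfg)
        d, v = random_input(cfg, batch=1)
        y1, w1 = predict(model, d[0], v[0])
        y2, w2 = predict(model, d[0], v[0])
        assert np.isfinite(y1)
        assert y1 == y2
        np.testing.assert_array_equal(w1, w2)

    def test_wrong_descriptor_length_rejected(self):
        model = init_model(small_config())
        with pytest.raises(ValueError):
            predict(model, np.zeros(99), np.zeros(6))

    def test_gradients_reach_every_parameter_group(self):
        cfg = small_config()
        model = init_model(cfg)
        d, v = random_input(cfg, batch=4)
        pred, _ = model.forward(d, v)
        err = pred - Tensor(np.ones(4))
        (err * err).mean().backward()
        for name, tensor in model.params.items():
            assert tensor.grad is not None and np.any(tensor.grad != 0), name

    def test_save_load_round_trip(self, tmp_path):
        cfg = small_config()
        model = init_model(cfg)
        model.vina_mean = np.arange(6.0)
        model.vina_std = np.arange(1.0, 7.0)
        d, v = random_input(cfg, batch=2)
        before, _ = predict_batch(model, d, v)
        model.save(tmp_path / "m.ckpt")
        loaded = Model.load(tmp_path / "m.ckpt")
        after, _ = predict_batch(loaded, d, v)
        np.testing.assert_allclose(before, after)


class TestAblations:
    @pytest.mark.parametrize(
        "use_vina,use_attention,has_attention_params",
        [(False, False, False), (False, True, True), (True, False, False), (True, True, True)],
    )
    def test_variants_are_constructible_and_wired(self, use_vina, use_attention, has_attention_params):
        cfg = small_config(use_vina=use_vina, use_attention=use_attention)
        model = init_model(cfg)
        assert ("q_w" in model.params) == has_attention_params
        d, v = random_input(cfg, batch=2)
        pred, weights = predict_batch(model, d, v)
        assert pred.shape == (2,)
        assert weights.shape == (2, cfg.u)

    def test_variants_have_distinct_parameter_sets(self):
        variants = [
            init_model(small_config(use_vina=uv, use_attention=ua))
            for uv in (False, True)
            for ua in (False, True)
        ]
        signatures = {
            (len(m.params), m.params["enc_w"].data.shape[0], "q_w" in m.params) for m in variants
        }
        assert len(signatures) == 4


class TestTraining:
    def _dataset(self, n, seed=0):
        spec = default_signal_spec(12, noise_sd=0.2)
        data, _ = generate_dataset(seed, n, 12, spec)
        return data

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_model([], [], small_config())

    def test_loss_decreases_on_learnable_signal(self):
        train = self._dataset(160, seed=1)
        cfg = small_config(epochs=6, batch_size=64)
        _, history = train_model(train, None, cfg)
        first = np.mean(history["train_loss"][:2])
        last = np.mean(history["train_loss"][-2:])
        assert last < first

    def test_strong_l2_collapses_predictions(self):
        train = self._dataset(160, seed=2)
        test = self._dataset(40, seed=3)
        D, V, _ = _stack_dataset(test)
        loose, _ = train_model(train, None, small_config(epochs=5, l2_lambda=1e-4))
        tight, _ = train_model(train, None, small_config(epochs=5, l2_lambda=50.0))
        pred_loose, _ = predict_batch(loose, D, V)
        pred_tight, _ = predict_batch(tight, D, V)
        assert np.var(pred_tight) < np.var(pred_loose)

    def test_best_validation_weights_are_restored(self):
        train = self._dataset(160, seed=4)
        valid = self._dataset(48, seed=5)
        cfg = small_config(epochs=8, batch_size=64)
        model, history = train_model(train, valid, cfg)
        D, V, y = _stack_dataset(valid)
        pred, _ = predict_batch(model, D, V)
        assert np.mean((pred - y) ** 2) == pytest.approx(min(history["valid_mse"]), rel=0.05)


class TestTopAttentionDescriptors:
    vocab = DescriptorVocabulary([f"d{i}" for i in range(10)])

    def test_full_fraction_returns_everything(self):
        weights = np.full(10, 0.1)
        assert len(top_attention_descriptors(weights, self.vocab, 1.0)) == 10

    def test_ten_percent_of_ten_is_the_argmax(self):
        weights = np.full(10, 0.05)
        weights[6] = 0.55
        assert top_attention_descriptors(weights, self.vocab, 0.1) == ["d6"]

    def test_ties_break_by_vocabulary_order(self):
        weights = np.full(10, 0.1)
        assert top_attention_descriptors(weights, self.vocab, 0.3) == ["d0", "d1", "d2"]

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            top_attention_descriptors(np.full(10, 0.1), self.vocab, 0.0)
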