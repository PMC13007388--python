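"""Transformer architecture: tokenization, equivariance, gradients, counts."""

import numpy as np
import pytest

from fiberparc import (
    ModelConfig,
    StreamlineTransformer,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
)
from fiberparc.model import cross_entropy


@pytest.fixture(scope="module")
def small_cfg():
    return ModelConfig(d_model=48, n_layers=2, ffn_hidden=32, clf_hidden=24,
                       n_classes=6, n_points=15, dropout=0.1)


@pytest.fixture(scope="module")
def model(small_cfg):
    return StreamlineTransformer(small_cfg, seed=0)


def _coords(rng, b=1, n=20, p=15):
    return rng.uniform(-1, 1, size=(b, n, p, 3)).astype(np.float32)


class TestConfig:
    def test_pad_linear_needs_room_for_coordinates(self):
        with pytest.raises(ValueError):
            ModelConfig(d_model=32, n_points=15)  # 45 > 32

    def test_head_divisibility(self):
        with pytest.raises(ValueError):
            ModelConfig(d_model=50, n_heads=4, n_points=15)


class TestTokenize:
    def test_first_entries_are_flattened_coordinates(self, model, rng):
        x = _coords(rng)
        tok = model.tokenize(x)
        np.testing.assert_array_equal(tok[..., :45], x.reshape(1, 20, 45))
        assert tok.shape == (1, 20, model.cfg.d_model)

    def test_zero_pad_layer_zero_input_gives_zero_token(self, small_cfg):
        m = StreamlineTransformer(small_cfg, seed=0)
        m.params["tok.Wpad"][:] = 0
        tok = m.tokenize(np.zeros((1, 3, 15, 3), dtype=np.float32))
        np.testing.assert_array_equal(tok, 0)

    def test_identical_streamlines_identical_tokens(self, model, rng):
        x = _coords(rng, n=5)
        x[0, 3] = x[0, 1]
        tok = model.tokenize(x)
        np.testing.assert_array_equal(tok[0, 3], tok[0, 1])

    def test_point_count_mismatch_is_an_error(self, model, rng):
        with pytest.raises(ValueError):
            model.tokenize(_coords(rng, p=10))


class TestEncoderInvariants:
    def test_permutation_equivariance(self, model, rng):
        """Reordering the context permutes the per-streamline logits."""
        x = _coords(rng, n=50)
        perm = rng.permutation(50)
        base = model.forward(x)
        permuted = model.forward(x[:, perm])
        assert np.max(np.abs(permuted - base[:, perm])) <= 1e-4

    @pytest.mark.parametrize("context", [1, 500, 2000])
    def test_variable_context_sizes_one_weight_set(self, model, rng, context):
        logits = model.forward(_coords(rng, n=context))
        assert logits.shape == (1, context, model.cfg.n_classes)
        assert np.all(np.isfinite(logits))

    def test_eval_mode_bit_identical(self, model, rng):
        x = _coords(rng, n=30)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_train_mode_dropout_is_stochastic(self, model, rng):
        x = _coords(rng, n=30)
        a = model.forward(x, train=True, rng=np.random.default_rng(0))
        b = model.forward(x, train=True, rng=np.random.default_rng(1))
        assert not np.array_equal(a, b)

    def test_duplicated_streamline_identical_logits(self, model, rng):
        x = _coords(rng, n=10)
        x[0, 7] = x[0, 2]
        logits = model.forward(x)
        np.testing.assert_allclose(logits[0, 7], logits[0, 2], atol=1e-5)

    def test_context_sensitivity(self, model, rng):
        """The same streamline under two disjoint contexts gets different
        logits: attention actually mixes information across streamlines."""
        probe = rng.uniform(-1, 1, size=(1, 15, 3)).astype(np.float32)
        ctx_a = _coords(rng, n=19)
        ctx_b = _coords(rng, n=19)
        la = model.forward(np.concatenate([probe[None], ctx_a], axis=1))[0, 0]
        lb = model.forward(np.concatenate([probe[None], ctx_b], axis=1))[0, 0]
        assert np.max(np.abs(la - lb)) > 1e-3

    def test_non_finite_input_is_an_error(self, model):
        x = np.full((1, 3, 15, 3), np.nan, dtype=np.float32)
        with pytest.raises(ValueError):
            model.forward(x)


class TestHead:
    def test_logit_shape_default_classes(self, rng):
        cfg = ModelConfig(d_model=48, n_layers=1, ffn_hidden=16, clf_hidden=16,
                          n_classes=1600, n_points=15)
        m = StreamlineTransformer(cfg, seed=0)
        logits = m.forward(_coords(rng, n=4))
        assert logits.shape == (1, 4, 1600)

    def test_zero_final_layer_gives_equal_logits(self, small_cfg, rng):
        m = StreamlineTransformer(small_cfg, seed=0)
        m.params["head.Wc"][:] = 0
        m.params["head.bc"][:] = 0
        logits = m.forward(_coords(rng, n=5))
        np.testing.assert_allclose(logits, 0, atol=1e-12)


class TestParameterCount:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {},
            {"n_layers": 0},
            {"n_heads": 2, "d_model": 64},
            {"token_mode": "projection", "d_model": 64},
            {"ffn_hidden": 512},
        ],
    )
    def test_formula_matches_instantiated_model(self, kwargs):
        cfg = ModelConfig(
            **{"d_model": 128, "n_layers": 2, "ffn_hidden": 256,
               "clf_hidden": 64, "n_classes": 10, "n_points": 15, **kwargs}
        )
        m = StreamlineTransformer(cfg, seed=0)
        assert m.n_parameters() == count_parameters(cfg)

    def test_doubling_ffn_changes_exactly_the_two_matrices(self):
        base = dict(d_model=64, n_layers=3, ffn_hidden=100, clf_hidden=16,
                    n_classes=5, n_points=15)
        a = count_parameters(ModelConfig(**base))
        b = count_parameters(ModelConfig(**{**base, "ffn_hidden": 200}))
        d, f = 64, 100
        expected_delta = 3 * (d * f + f + f * d)  # W1, b1, W2 grow per layer
        assert b - a == expected_delta

    def test_default_config_count_frozen(self):
        # regression constant computed once from the closed-form layer sums
        assert count_parameters(ModelConfig()) == 1_507_799


class TestGradients:
    @pytest.mark.parametrize("token_mode", ["pad_linear", "projection"])
    def test_backward_matches_finite_differences(self, token_mode):
        cfg = ModelConfig(d_model=8, n_layers=2, n_heads=2, ffn_hidden=5,
                          clf_hidden=6, n_classes=4, n_points=2, dropout=0.0,
                          token_mode=token_mode)
        m = StreamlineTransformer(cfg, seed=3)
        m.params = {k: v.astype(np.float64) for k, v in m.params.items()}
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, (2, 5, 2, 3))
        y = rng.integers(0, 4, (2, 5))
        logits, cache = m.forward(x, return_cache=True)
        _, dlogits = cross_entropy(logits, y)
        grads = m.backward(dlogits, cache)
        eps = 1e-6
        check_rng = np.random.default_rng(1)
        for k, w in m.params.items():
            flat = check_rng.choice(w.size, size=min(4, w.size), replace=False)
            for i in flat:
                ix = np.unravel_index(i, w.shape)
                orig = w[ix]
                w[ix] = orig + eps
                lp = cross_entropy(m.forward(x), y)[0]
                w[ix] = orig - eps
                lm = cross_entropy(m.forward(x), y)[0]
                w[ix] = orig
                num = (lp - lm) / (2 * eps)
                # combined tolerance: the key-bias gradient is exactly 0
                # (softmax row-shift invariance), where finite differences
                # only deliver noise-level agreement
                err = abs(num - grads[k][ix])
                assert err < 1e-8 + 1e-4 * (abs(num) + abs(grads[k][ix])), k


def test_cross_entropy_matches_log_softmax_oracle(rng):
    logits = rng.normal(size=(2, 7, 5)).astype(np.float32)
    y = rng.integers(0, 5, (2, 7))
    loss, _ = cross_entropy(logits, y)
    from scipy.special import log_softmax
    expected = -log_softmax(logits, axis=-1)[
        np.arange(2)[:, None], np.arange(7)[None, :], y
    ].mean()
    assert abs(loss - expected) < 1e-6


def test_checkpoint_round_trip(tmp_path, small_cfg, rng):
    m = StreamlineTransformer(small_cfg, seed=7)
    class_ids = np.arange(small_cfg.n_classes)
    path = tmp_path / "model.npz"
    save_checkpoint(path, m, class_ids=class_ids, extra={"note": "test"})
    back, ids, header = load_checkpoint(path)
    np.testing.assert_array_equal(ids, class_ids)
    assert header["extra"]["note"] == "test"
    x = _coords(rng, n=6)
    np.testing.assert_array_equal(back.forward(x), m.forward(x))
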