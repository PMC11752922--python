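"""Architecture correctness against independent numpy recomputations."""

import numpy as np
import pytest

from losformer.autodiff import Tensor
from losformer.model import (
    ModelConfig,
    attention_encoder,
    attention_weights,
    embed,
    init_params,
    load_params,
    param_count,
    predict,
    save_params,
    skip_token_head,
)


@pytest.fixture
def tiny():
    cfg = ModelConfig(col=3, d=2, n_heads=1, seed=5)
    return cfg, init_params(cfg)


class TestInit:
    def test_cls_token_starts_at_zero(self):
        params = init_params(ModelConfig(d=40, n_heads=5))
        np.testing.assert_array_equal(params["cls"].data, np.zeros(40))

    def test_seed_determinism(self):
        a = init_params(ModelConfig(seed=3))
        b = init_params(ModelConfig(seed=3))
        for k in a.weights:
            np.testing.assert_array_equal(a[k].data, b[k].data)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(d=41, n_heads=5)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            ModelConfig(mode="sideways")

    def test_bn_stats_start_at_identity(self):
        p = init_params(ModelConfig())
        np.testing.assert_array_equal(p.stats["bn_in_mean"], 0)
        np.testing.assert_array_equal(p.stats["bn_in_var"], 1)

    def test_param_count_formula(self):
        for cfg in (
            ModelConfig(),
            ModelConfig(col=3, d=2, n_heads=1),
            ModelConfig(n_blocks=2),
            ModelConfig(shared_tokenizer=True),
        ):
            p = init_params(cfg)
            actual = sum(t.data.size for t in p.trainable())
            assert actual == param_count(cfg)


class TestEmbed:
    def test_zero_input_gives_bias_tokens(self, tiny):
        cfg, p = tiny
        p["emb_b"].data[:] = 0.0
        p["cls"].data[:] = [1.0, 2.0]
        toks = embed(Tensor(np.zeros((2, 3))), p).data
        assert toks.shape == (2, 4, 2)
        np.testing.assert_array_equal(toks[:, 0], [[1, 2], [1, 2]])
        np.testing.assert_array_equal(toks[:, 1:], 0)

    def test_per_position_locality(self, tiny):
        cfg, p = tiny
        x = np.array([[1.0, 2.0, 3.0]])
        x2 = x.copy()
        x2[0, 2] *= 2
        t1 = embed(Tensor(x), p).data
        t2 = embed(Tensor(x2), p).data
        np.testing.assert_array_equal(t1[:, :3], t2[:, :3])  # CLS + feats 0,1
        delta = t2[0, 3] - t1[0, 3]
        np.testing.assert_allclose(delta, 3.0 * p["emb_W"].data[2], atol=1e-12)

    def test_matches_affine_bruteforce(self, tiny):
        cfg, p = tiny
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 3))
        toks = embed(Tensor(x), p).data
        for b in range(4):
            np.testing.assert_allclose(toks[b, 0], p["cls"].data, atol=1e-12)
            for i in range(3):
                expected = x[b, i] * p["emb_W"].data[i] + p["emb_b"].data[i]
                np.testing.assert_allclose(toks[b, i + 1], expected, atol=1e-12)

    def test_shared_tokenizer_uses_one_map(self):
        cfg = ModelConfig(col=3, d=2, n_heads=1, shared_tokenizer=True, seed=1)
        p = init_params(cfg)
        x = np.array([[2.0, 2.0, 2.0]])
        toks = embed(Tensor(x), p).data
        np.testing.assert_allclose(toks[0, 1], toks[0, 2], atol=1e-12)
        np.testing.assert_allclose(toks[0, 2], toks[0, 3], atol=1e-12)

    def test_wrong_length_rejected(self, tiny):
        cfg, p = tiny
        with pytest.raises(ValueError):
            embed(Tensor(np.zeros((1, 5))), p)


def encoder_oracle(tokens, p, d, eps=1e-5):
    """Plain-numpy single-head post-norm encoder block."""

    def ln(x, g, b):
        mu = x.mean(-1, keepdims=True)
        var = ((x - mu) ** 2).mean(-1, keepdims=True)
        return (x - mu) / np.sqrt(var + eps) * g + b

    q = tokens @ p["blk0_Wq"].data + p["blk0_bq"].data
    k = tokens @ p["blk0_Wk"].data + p["blk0_bk"].data
    v = tokens @ p["blk0_Wv"].data + p["blk0_bv"].data
    scores = q @ k.swapaxes(-1, -2) / np.sqrt(d)
    e = np.exp(scores - scores.max(-1, keepdims=True))
    attn = e / e.sum(-1, keepdims=True)
    msa = (attn @ v) @ p["blk0_Wo"].data + p["blk0_bo"].data
    h = ln(tokens + msa, p["blk0_ln1_g"].data, p["blk0_ln1_b"].data)
    ffn = (
        np.maximum(h @ p["blk0_ffn_W1"].data + p["blk0_ffn_b1"].data, 0)
        @ p["blk0_ffn_W2"].data
        + p["blk0_ffn_b2"].data
    )
    return ln(h + ffn, p["blk0_ln2_g"].data, p["blk0_ln2_b"].data)


class TestAttentionEncoder:
    def test_matches_bruteforce_oracle(self, tiny):
        cfg, p = tiny
        rng = np.random.default_rng(1)
        toks = rng.normal(size=(2, 4, 2))
        out = attention_encoder(Tensor(toks), p).data
        np.testing.assert_allclose(out, encoder_oracle(toks, p, d=2), atol=1e-10)

    def test_attention_rows_sum_to_one(self):
        cfg = ModelConfig(col=16, d=40, n_heads=5, seed=2)
        p = init_params(cfg)
        toks = np.random.default_rng(3).normal(size=(3, 17, 40))
        w = attention_weights(toks, p)
        assert w.shape == (3, 5, 17, 17)
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_identical_tokens_give_identical_outputs(self, tiny):
        cfg, p = tiny
        row = np.array([0.3, -0.7])
        toks = np.tile(row, (1, 4, 1))
        out = attention_encoder(Tensor(toks), p).data
        for t in range(4):
            np.testing.assert_allclose(out[0, t], out[0, 0], atol=1e-10)

    def test_shape_preserved_multihead(self):
        cfg = ModelConfig(col=5, d=6, n_heads=3, seed=0)
        p = init_params(cfg)
        toks = np.random.default_rng(1).normal(size=(2, 6, 6))
        out = attention_encoder(Tensor(toks), p).data
        assert out.shape == (2, 6, 6)


class TestSkipTokenHead:
    def test_zero_weights_predict_zero(self, tiny):
        cfg, p = tiny
        for k in ("fuse_f_W", "fuse_f_b", "fuse_t_W", "fuse_t_b", "head_W", "head_b"):
            p[k].data[:] = 0.0
        toks = np.random.default_rng(2).normal(size=(3, 4, 2))
        out = skip_token_head(Tensor(toks), p).data
        np.testing.assert_array_equal(out, 0.0)

    def test_global_mode_ignores_feature_tokens(self, tiny):
        cfg, p = tiny
        rng = np.random.default_rng(4)
        toks = rng.normal(size=(2, 4, 2))
        perturbed = toks.copy()
        perturbed[:, 1:, :] += rng.normal(size=(2, 3, 2))
        a = skip_token_head(Tensor(toks), p, mode="global_only").data
        b = skip_token_head(Tensor(perturbed), p, mode="global_only").data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_both_mode_matches_bruteforce(self, tiny):
        cfg, p = tiny
        rng = np.random.default_rng(5)
        toks = rng.normal(size=(3, 4, 2))
        flat = toks.reshape(3, 8)  # eval-mode BN at identity stats
        flat = (flat / np.sqrt(1 + 1e-5)) * p["bn_out_gamma"].data + p[
            "bn_out_beta"
        ].data
        cls, fp = flat[:, :2], flat[:, 2:]
        f = fp @ p["fuse_f_W"].data + p["fuse_f_b"].data
        t = (cls + f) @ p["fuse_t_W"].data + p["fuse_t_b"].data
        expected = (t @ p["head_W"].data + p["head_b"].data).ravel()
        out = skip_token_head(Tensor(toks), p, mode="both").data
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_zeroed_fusion_degenerates_to_global(self, tiny):
        cfg, p = tiny
        p["fuse_f_W"].data[:] = 0.0
        p["fuse_f_b"].data[:] = 0.0
        toks = np.random.default_rng(6).normal(size=(4, 4, 2))
        both = skip_token_head(Tensor(toks), p, mode="both").data
        glob = skip_token_head(Tensor(toks), p, mode="global_only").data
        np.testing.assert_allclose(both, glob, atol=1e-12)

    def test_unknown_mode_rejected(self, tiny):
        cfg, p = tiny
        toks = np.zeros((1, 4, 2))
        with pytest.raises(ValueError, match="mode"):
            skip_token_head(Tensor(toks), p, mode="wat")


class TestPredict:
    def test_identical_rows_identical_predictions(self):
        p = init_params(ModelConfig(col=4, d=4, n_heads=2, seed=7))
        x = np.tile([0.1, -0.2, 0.3, 0.0], (5, 1))
        out = predict(x, p)
        np.testing.assert_allclose(out, out[0], atol=1e-12)

    def test_batch_composition_independence(self):
        p = init_params(ModelConfig(col=4, d=4, n_heads=2, seed=8))
        rng = np.random.default_rng(9)
        batch = rng.normal(size=(6, 4))
        full = predict(batch, p)
        solo = np.array([predict(batch[i : i + 1], p)[0] for i in range(6)])
        np.testing.assert_allclose(full, solo, atol=1e-6)

    def test_column_mismatch_rejected(self):
        p = init_params(ModelConfig(col=4, d=4, n_heads=2))
        with pytest.raises(ValueError):
            predict(np.zeros((2, 5)), p)

    def test_feature_permutation_consistency(self):
        """Permuting features together with every position-indexed
        parameter block leaves predictions unchanged."""
        cfg = ModelConfig(col=5, d=4, n_heads=2, seed=10)
        p = init_params(cfg)
        rng = np.random.default_rng(11)
        # non-trivial BN stats and CLS so all paths are exercised
        p["cls"].data[:] = rng.normal(size=4)
        p.stats["bn_in_mean"] = rng.normal(size=5)
        p.stats["bn_in_var"] = rng.uniform(0.5, 2.0, size=5)
        x = rng.normal(size=(3, 5))
        base = predict(x, p)

        perm = np.array([3, 0, 4, 1, 2])
        q = p.copy()
        q["emb_W"].data[:] = p["emb_W"].data[perm]
        q["emb_b"].data[:] = p["emb_b"].data[perm]
        q["bn_in_gamma"].data[:] = p["bn_in_gamma"].data[perm]
        q["bn_in_beta"].data[:] = p["bn_in_beta"].data[perm]
        q.stats["bn_in_mean"] = p.stats["bn_in_mean"][perm]
        q.stats["bn_in_var"] = p.stats["bn_in_var"][perm]
        d = cfg.d
        # feature blocks of the flattened token vector shift by one (CLS first)
        blocks = np.concatenate([[0], 1 + perm])
        chan = np.concatenate([np.arange(b * d, (b + 1) * d) for b in blocks])
        q["bn_out_gamma"].data[:] = p["bn_out_gamma"].data[chan]
        q["bn_out_beta"].data[:] = p["bn_out_beta"].data[chan]
        q.stats["bn_out_mean"] = p.stats["bn_out_mean"][chan]
        q.stats["bn_out_var"] = p.stats["bn_out_var"][chan]
        fchan = np.concatenate([np.arange(i * d, (i + 1) * d) for i in perm])
        q["fuse_f_W"].data[:] = p["fuse_f_W"].data[fchan]
        out = predict(x[:, perm], q)
        np.testing.assert_allclose(out, base, atol=1e-6)


def test_checkpoint_roundtrip(tmp_path):
    cfg = ModelConfig(col=4, d=4, n_heads=2, seed=12)
    p = init_params(cfg)
    p.stats["bn_in_mean"] += 0.5
    path = tmp_path / "ckpt.npz"
    save_params(p, path)
    q = load_params(path)
    assert q.config == cfg
    for k in p.weights:
        np.testing.assert_array_equal(p[k].data, q[k].data)
    np.testing.assert_array_equal(p.stats["bn_in_mean"], q.stats["bn_in_mean"])
    x = np.random.default_rng(13).normal(size=(2, 4))
    np.testing.assert_array_equal(predict(x, p), predict(x, q))
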