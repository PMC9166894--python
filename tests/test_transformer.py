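"""Attention mechanics, forward contract, and training."""

import numpy as np
import pytest
from scipy.special import erf

from itemforge.transformer import (
    DivergenceError,
    ModelConfig,
    ShapeError,
    TrainSchedule,
    attention_layer,
    causal_mask,
    forward,
    init_params,
    loss_and_grads,
    softmax_tau,
    train,
)


class TestCausalMask:
    def test_single_position(self):
        m = causal_mask(1)
        assert m.shape == (1, 1) and m[0, 0] == 0

    def test_lower_triangle_counts(self):
        m = causal_mask(3)
        assert np.isfinite(m).sum() == 6  # lower triangle incl. diagonal
        assert np.isneginf(m).sum() == 3

    def test_masked_softmax_rows_stochastic(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(8, 8)) + causal_mask(8)
        probs = softmax_tau(scores)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.all(probs[np.triu_indices(8, k=1)] == 0.0)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ShapeError):
            causal_mask(0)


class TestSoftmaxTau:
    def test_symmetry(self):
        for tau in (0.5, 1.0, 7.0):
            assert np.allclose(softmax_tau(np.zeros(2), tau), [0.5, 0.5])

    def test_direct_evaluation(self):
        # e^a / sum e^a for a = (1, 2, 3)
        assert np.allclose(
            softmax_tau(np.array([1.0, 2.0, 3.0])),
            [0.0900, 0.2447, 0.6652],
            atol=5e-5,
        )

    def test_temperature_limits(self):
        a = np.array([1.0, 2.0, 3.0])
        hot = softmax_tau(a, tau=100.0)
        assert np.all(np.abs(hot - 1 / 3) < 0.01)  # toward uniform
        cold = softmax_tau(a, tau=0.01)
        assert cold[2] > 0.999  # toward one-hot at argmax

    def test_shift_stability(self):
        a = np.array([1000.0, 1001.0, 999.0])
        assert np.allclose(softmax_tau(a), softmax_tau(a - 1000.0))

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            softmax_tau(np.ones(3), tau=0.0)


def reference_block(x, p, prefix, cfg):
    """Independent re-computation of one pre-norm block with explicit
    loops over heads (oracle for attention_layer)."""
    def ln(v, g, b):
        mu, var = v.mean(-1, keepdims=True), v.var(-1, keepdims=True)
        return g * (v - mu) / np.sqrt(var + 1e-5) + b

    n, d = x.shape
    h1 = ln(x, p[prefix + "ln1_g"], p[prefix + "ln1_b"])
    hd = cfg.d_head
    heads = []
    for h in range(cfg.n_heads):
        sl = slice(h * hd, (h + 1) * hd)
        q = (h1 @ p[prefix + "Wq"])[:, sl]
        k = (h1 @ p[prefix + "Wk"])[:, sl]
        v = (h1 @ p[prefix + "Wv"])[:, sl]
        scale = np.sqrt(hd if cfg.scale == "head_dim" else n)
        z = np.zeros((n, hd))
        for i in range(n):
            scores = np.array([q[i] @ k[j] / scale for j in range(i + 1)])
            w = np.exp(scores - scores.max())
            w /= w.sum()
            z[i] = sum(w[j] * v[j] for j in range(i + 1))
        heads.append(z)
    att = np.concatenate(heads, axis=1) @ p[prefix + "Wo"]
    x1 = x + att
    h2 = ln(x1, p[prefix + "ln2_g"], p[prefix + "ln2_b"])
    a = h2 @ p[prefix + "W1"] + p[prefix + "b1"]
    gelu = 0.5 * a * (1 + erf(a / np.sqrt(2)))
    return x1 + gelu @ p[prefix + "W2"] + p[prefix + "b2"]


class TestAttentionLayer:
    def test_matches_explicit_loop_oracle(self):
        cfg = ModelConfig(vocab_size=5, d_model=4, n_heads=2, n_layers=1,
                          n_ctx=6, d_ff=8, seed=9, init_std=0.7)
        p = init_params(cfg)
        x = np.random.default_rng(1).normal(size=(5, 4))
        assert np.allclose(
            attention_layer(x, p, 0, cfg), reference_block(x, p, "l0.", cfg)
        )

    def test_seq_len_scaling_option(self):
        cfg = ModelConfig(vocab_size=5, d_model=4, n_heads=1, n_layers=1,
                          n_ctx=6, d_ff=8, seed=9, scale="seq_len", init_std=0.7)
        p = init_params(cfg)
        x = np.random.default_rng(2).normal(size=(4, 4))
        assert np.allclose(
            attention_layer(x, p, 0, cfg), reference_block(x, p, "l0.", cfg)
        )

    def test_causality_perturbation_invariance(self):
        cfg = ModelConfig(vocab_size=5, d_model=8, n_heads=2, n_layers=1,
                          n_ctx=8, d_ff=16, seed=4, init_std=0.5)
        p = init_params(cfg)
        x = np.random.default_rng(3).normal(size=(5, 8))
        base = attention_layer(x, p, 0, cfg)
        x2 = x.copy()
        x2[3] += 10.0  # perturb position 3 (0-based index 3)
        pert = attention_layer(x2, p, 0, cfg)
        assert np.array_equal(base[:3], pert[:3])  # bit-identical before it

    def test_shape_mismatch_rejected(self):
        cfg = ModelConfig(vocab_size=5, d_model=8, n_heads=2, n_layers=1,
                          n_ctx=8, d_ff=16)
        with pytest.raises(ShapeError, match="d_model"):
            attention_layer(np.zeros((3, 5)), init_params(cfg), 0, cfg)


class TestForward:
    @pytest.fixture()
    def model(self):
        cfg = ModelConfig(vocab_size=9, d_model=8, n_heads=2, n_layers=2,
                          n_ctx=10, d_ff=16, seed=5, init_std=0.4)
        return init_params(cfg), cfg

    def test_rows_are_distributions(self, model):
        p, cfg = model
        probs = forward([1, 4, 2, 7], p, cfg)
        assert probs.shape == (4, 9)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_causal_output_invariance(self, model):
        p, cfg = model
        a = forward([1, 2, 3, 4, 5], p, cfg)
        b = forward([1, 2, 3, 8, 6], p, cfg)
        assert np.allclose(a[:3], b[:3])

    def test_zero_weights_give_uniform(self):
        cfg = ModelConfig(vocab_size=6, d_model=8, n_heads=2, n_layers=1,
                          n_ctx=6, d_ff=16, seed=0)
        p = {k: np.zeros_like(v) for k, v in init_params(cfg).items()}
        probs = forward([1, 2, 3], p, cfg)
        assert np.allclose(probs, 1 / 6)

    def test_out_of_range_id_rejected(self, model):
        p, cfg = model
        with pytest.raises(ShapeError):
            forward([0, 99], p, cfg)


@pytest.mark.parametrize(
    "kwargs",
    [
        {},  # defaults: pre-norm, head_dim scaling, learned positions
        {"norm": "post", "scale": "seq_len", "positional": "sinusoidal"},
    ],
    ids=["pre_norm", "post_norm_seqlen_sinusoidal"],
)
def test_gradients_match_central_differences(kwargs):
    cfg = ModelConfig(vocab_size=7, d_model=8, n_heads=2, n_layers=2,
                      n_ctx=6, d_ff=12, seed=3, **kwargs)
    p = init_params(cfg)
    batch = np.array([[1, 2, 3, 4, 5, 2], [2, 3, 1, 0, 0, 0]])
    mask = np.array([[1] * 6, [1, 1, 1, 0, 0, 0]], dtype=bool)
    _, grads = loss_and_grads(batch, mask, p, cfg)
    rng = np.random.default_rng(0)
    eps = 1e-5
    for name, arr in p.items():
        for _ in range(3):
            idx = tuple(rng.integers(s) for s in arr.shape)
            arr[idx] += eps
            l1, _ = loss_and_grads(batch, mask, p, cfg)
            arr[idx] -= 2 * eps
            l2, _ = loss_and_grads(batch, mask, p, cfg)
            arr[idx] += eps
            num = (l1 - l2) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, rel=5e-3, abs=1e-7), name


class TestTrain:
    def test_initial_loss_near_log_vocab(self):
        cfg = ModelConfig(vocab_size=20, d_model=8, n_heads=2, n_layers=1,
                          n_ctx=8, d_ff=16, seed=1)
        corpus = [[1, 5, 7, 2], [3, 8, 9, 11, 2]]
        _, trace = train(corpus, cfg, TrainSchedule(steps=1))
        assert trace[0] == pytest.approx(np.log(20), abs=0.05)

    def test_identical_seeds_identical_traces(self):
        cfg = ModelConfig(vocab_size=12, d_model=8, n_heads=2, n_layers=1,
                          n_ctx=8, d_ff=16, seed=7)
        corpus = [[1, 5, 7, 2], [3, 8, 9, 2]]
        _, t1 = train(corpus, cfg, TrainSchedule(steps=30))
        _, t2 = train(corpus, cfg, TrainSchedule(steps=30))
        assert t1 == t2

    def test_loss_decreases(self):
        cfg = ModelConfig(vocab_size=12, d_model=16, n_heads=2, n_layers=1,
                          n_ctx=8, d_ff=32, seed=7)
        corpus = [[1, 5, 7, 2], [3, 8, 9, 2], [4, 4, 6, 2]]
        _, trace = train(corpus, cfg, TrainSchedule(steps=300, lr=5e-3))
        assert trace[-1] < 0.5 * trace[0]

    def test_divergence_aborts_with_diagnostic(self):
        cfg = ModelConfig(vocab_size=12, d_model=8, n_heads=2, n_layers=1,
                          n_ctx=8, d_ff=16, seed=7)
        with pytest.raises(DivergenceError):
            train([[1, 5, 2]], cfg,
                  TrainSchedule(steps=200, lr=1e6, optimizer="sgd"))

    def test_too_long_sequence_rejected(self):
        cfg = ModelConfig(vocab_size=12, d_model=8, n_heads=2, n_layers=1,
                          n_ctx=3, d_ff=16)
        with pytest.raises(ShapeError):
            train([[1, 2, 3, 4, 5]], cfg)
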