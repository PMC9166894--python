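"""Miniature decoder-only causal transformer, pure numpy.

Implements the standard attention stack — token + positional embeddings,
multi-head masked self-attention ``Z = softmax(Q K^T / scale) V`` per head,
concatenation and output projection, layer normalization, and a
position-wise feed-forward network — with the output projection weight-tied
to the token embedding matrix.  Gradients are computed by hand-written
reverse-mode passes over the same caches the forward pass produces; the
reference path is CPU-only float64, sized for desk-scale corpora of a few
dozen short sequences rather than web-scale text.

Two conventions are configurable because the field uses both:

* ``scale``: attention scores are divided by ``sqrt(d/n_h)`` (per-head key
  dimension, the GPT-2 convention, default) or by ``sqrt(n)`` (sequence
  length).
* ``norm``: pre-norm (default, stable at tiny scale) or post-norm block
  ordering; ``positional``: learned (default) or sinusoidal encodings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import erf

__all__ = [
    "ModelConfig",
    "TrainSchedule",
    "TransformerParams",
    "causal_mask",
    "softmax_tau",
    "attention_layer",
    "init_params",
    "forward",
    "loss_and_grads",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


class ShapeError(ValueError):
    """Raised when an input violates a declared shape contract."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``d_model`` must be divisible by ``n_heads``; ``n_ctx`` bounds the
    longest sequence the model can score.
    """

    vocab_size: int
    d_model: int = 32
    n_heads: int = 2
    n_layers: int = 2
    n_ctx: int = 32
    d_ff: int = 64
    seed: int = 0
    scale: str = "head_dim"  # "head_dim" | "seq_len"
    positional: str = "learned"  # "learned" | "sinusoidal"
    norm: str = "pre"  # "pre" | "post"
    init_std: float = 0.02

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ShapeError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        for name in ("vocab_size", "d_model", "n_heads", "n_layers", "n_ctx", "d_ff"):
            if getattr(self, name) < 1:
                raise ShapeError(f"{name} must be >= 1")
        if self.scale not in ("head_dim", "seq_len"):
            raise ValueError(f"unknown scale convention {self.scale!r}")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class TrainSchedule:
    steps: int = 2000
    lr: float = 5e-4
    optimizer: str = "adam"  # "adam" | "momentum" | "sgd"
    momentum: float = 0.9
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    log_every: int = 50


#: parameter dictionary: name -> ndarray.  Per layer i the names are
#: ``l{i}.{ln1_g,ln1_b,Wq,Wk,Wv,Wo,ln2_g,ln2_b,W1,b1,W2,b2}``; globally
#: ``tok_emb``, ``pos_emb`` (absent when sinusoidal), ``lnf_g``, ``lnf_b``.
TransformerParams = dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def causal_mask(n: int) -> np.ndarray:
    """Additive attention mask: 0 where position i may attend to j (j <= i),
    -inf where j > i, so that masked entries carry exactly zero weight after
    the softmax."""
    if n < 1:
        raise ShapeError("sequence length must be >= 1")
    mask = np.zeros((n, n))
    mask[np.triu_indices(n, k=1)] = -np.inf
    return mask


def softmax_tau(a: np.ndarray, tau: float = 1.0, axis: int = -1) -> np.ndarray:
    """Temperature softmax ``exp(a/tau) / sum exp(a_i/tau)``.

    Numerically stabilized by max-subtraction; -inf entries (mask
    sentinels) map to exactly 0.  tau > 1 flattens the distribution toward
    uniform, tau -> 0+ approaches one-hot at the argmax.
    """
    if tau <= 0:
        raise ValueError(f"temperature must be positive, got {tau}")
    a = np.asarray(a, dtype=float) / tau
    shift = np.max(a, axis=axis, keepdims=True)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    e = np.exp(a - shift)
    return e / np.sum(e, axis=axis, keepdims=True)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * np.exp(-0.5 * x * x) / np.sqrt(
        2.0 * np.pi
    )


def _ln_fwd(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_bwd(dy, cache):
    xhat, inv, g = cache
    d = xhat.shape[-1]
    dg = (dy * xhat).sum(tuple(range(dy.ndim - 1)))
    db = dy.sum(tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    assert d == xhat.shape[-1]
    return dx, dg, db


def _split_heads(x, n_heads):  # (B,n,d) -> (B,h,n,hd)
    B, n, d = x.shape
    return x.reshape(B, n, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):  # (B,h,n,hd) -> (B,n,d)
    B, h, n, hd = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, n, h * hd)


def _attn_fwd(x, p, prefix, mask, cfg: ModelConfig):
    q = _split_heads(x @ p[prefix + "Wq"], cfg.n_heads)
    k = _split_heads(x @ p[prefix + "Wk"], cfg.n_heads)
    v = _split_heads(x @ p[prefix + "Wv"], cfg.n_heads)
    n = x.shape[1]
    scale = np.sqrt(cfg.d_head if cfg.scale == "head_dim" else n)
    scores = q @ k.transpose(0, 1, 3, 2) / scale + mask
    att = softmax_tau(scores, 1.0, axis=-1)
    z = att @ v
    merged = _merge_heads(z)
    out = merged @ p[prefix + "Wo"]
    return out, (x, q, k, v, att, merged, scale)


def _attn_bwd(dout, cache, p, prefix, cfg: ModelConfig, grads):
    x, q, k, v, att, merged, scale = cache
    grads[prefix + "Wo"] += np.einsum("bnd,bne->de", merged, dout)
    dmerged = dout @ p[prefix + "Wo"].T
    dz = _split_heads(dmerged, cfg.n_heads)
    datt = dz @ v.transpose(0, 1, 3, 2)
    dv = att.transpose(0, 1, 3, 2) @ dz
    # softmax jacobian, rowwise
    dscores = att * (datt - (datt * att).sum(-1, keepdims=True))
    dscores /= scale
    dq = dscores @ k
    dk = dscores.transpose(0, 1, 3, 2) @ q
    dx = np.zeros_like(x)
    for name, dh in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
        dflat = _merge_heads(dh)
        grads[prefix + name] += np.einsum("bnd,bne->de", x, dflat)
        dx += dflat @ p[prefix + name].T
    return dx


def _ff_fwd(x, p, prefix):
    a = x @ p[prefix + "W1"] + p[prefix + "b1"]
    h = _gelu(a)
    return h @ p[prefix + "W2"] + p[prefix + "b2"], (x, a, h)


def _ff_bwd(dout, cache, p, prefix, grads):
    x, a, h = cache
    grads[prefix + "W2"] += np.einsum("bnd,bne->de", h, dout)
    grads[prefix + "b2"] += dout.sum((0, 1))
    dh = dout @ p[prefix + "W2"].T
    da = dh * _gelu_grad(a)
    grads[prefix + "W1"] += np.einsum("bnd,bne->de", x, da)
    grads[prefix + "b1"] += da.sum((0, 1))
    return da @ p[prefix + "W1"].T


def _block_fwd(x, p, i, mask, cfg: ModelConfig):
    pre = f"l{i}."
    if cfg.norm == "pre":
        h1, c_ln1 = _ln_fwd(x, p[pre + "ln1_g"], p[pre + "ln1_b"])
        a, c_att = _attn_fwd(h1, p, pre, mask, cfg)
        x1 = x + a
        h2, c_ln2 = _ln_fwd(x1, p[pre + "ln2_g"], p[pre + "ln2_b"])
        f, c_ff = _ff_fwd(h2, p, pre)
        out = x1 + f
    else:  # post-norm
        a, c_att = _attn_fwd(x, p, pre, mask, cfg)
        x1, c_ln1 = _ln_fwd(x + a, p[pre + "ln1_g"], p[pre + "ln1_b"])
        f, c_ff = _ff_fwd(x1, p, pre)
        out, c_ln2 = _ln_fwd(x1 + f, p[pre + "ln2_g"], p[pre + "ln2_b"])
    return out, (c_ln1, c_att, c_ln2, c_ff)


def _block_bwd(dout, cache, p, i, cfg: ModelConfig, grads):
    pre = f"l{i}."
    c_ln1, c_att, c_ln2, c_ff = cache
    if cfg.norm == "pre":
        # residual: out = x1 + ff(ln2(x1))
        dff_in = _ff_bwd(dout, c_ff, p, pre, grads)
        dx1_from_ln, dg2, db2 = _ln_bwd(dff_in, c_ln2)
        grads[pre + "ln2_g"] += dg2
        grads[pre + "ln2_b"] += db2
        dx1 = dout + dx1_from_ln
        # residual: x1 = x + attn(ln1(x))
        datt_in = _attn_bwd(dx1, c_att, p, pre, cfg, grads)
        dx_from_ln, dg1, db1 = _ln_bwd(datt_in, c_ln1)
        grads[pre + "ln1_g"] += dg1
        grads[pre + "ln1_b"] += db1
        return dx1 + dx_from_ln
    # post-norm: out = ln2(x1 + ff(x1)), x1 = ln1(x + attn(x))
    dsum2, dg2, db2 = _ln_bwd(dout, c_ln2)
    grads[pre + "ln2_g"] += dg2
    grads[pre + "ln2_b"] += db2
    dx1 = dsum2 + _ff_bwd(dsum2, c_ff, p, pre, grads)
    dsum1, dg1, db1 = _ln_bwd(dx1, c_ln1)
    grads[pre + "ln1_g"] += dg1
    grads[pre + "ln1_b"] += db1
    return dsum1 + _attn_bwd(dsum1, c_att, p, pre, cfg, grads)


def attention_layer(
    x: np.ndarray, params: TransformerParams, layer: int, cfg: ModelConfig
) -> np.ndarray:
    """One full transformer block (masked multi-head attention, output
    projection, normalization, feed-forward) applied to an n x d input."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != cfg.d_model:
        raise ShapeError(
            f"input must be n x d_model={cfg.d_model}, got shape {x.shape}"
        )
    n = x.shape[0]
    if n > cfg.n_ctx:
        raise ShapeError(f"sequence length {n} exceeds context {cfg.n_ctx}")
    out, _ = _block_fwd(x[None], params, layer, causal_mask(n), cfg)
    return out[0]


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------


def _sinusoidal(n_ctx: int, d: int) -> np.ndarray:
    pos = np.arange(n_ctx)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


def init_params(cfg: ModelConfig) -> TransformerParams:
    """Small seeded Gaussian initialization; norm gains start at 1."""
    rng = np.random.default_rng(cfg.seed)
    s = cfg.init_std
    d, dff = cfg.d_model, cfg.d_ff
    p: TransformerParams = {
        "tok_emb": rng.normal(0, s, (cfg.vocab_size, d)),
    }
    if cfg.positional == "learned":
        p["pos_emb"] = rng.normal(0, s, (cfg.n_ctx, d))
    for i in range(cfg.n_layers):
        pre = f"l{i}."
        for w in ("Wq", "Wk", "Wv", "Wo"):
            p[pre + w] = rng.normal(0, s, (d, d))
        p[pre + "W1"] = rng.normal(0, s, (d, dff))
        p[pre + "b1"] = np.zeros(dff)
        p[pre + "W2"] = rng.normal(0, s, (dff, d))
        p[pre + "b2"] = np.zeros(d)
        for g in ("ln1", "ln2"):
            p[pre + g + "_g"] = np.ones(d)
            p[pre + g + "_b"] = np.zeros(d)
    p["lnf_g"] = np.ones(d)
    p["lnf_b"] = np.zeros(d)
    return p


def _embed(ids: np.ndarray, p: TransformerParams, cfg: ModelConfig) -> np.ndarray:
    n = ids.shape[1]
    pos = p["pos_emb"][:n] if cfg.positional == "learned" else _sinusoidal(
        cfg.n_ctx, cfg.d_model
    )[:n]
    return p["tok_emb"][ids] + pos


def _forward_batch(ids: np.ndarray, p: TransformerParams, cfg: ModelConfig):
    """Logits (B,n,V) plus caches for the backward pass."""
    B, n = ids.shape
    mask = causal_mask(n)
    x = _embed(ids, p, cfg)
    caches = []
    for i in range(cfg.n_layers):
        x, c = _block_fwd(x, p, i, mask, cfg)
        caches.append(c)
    h, c_lnf = _ln_fwd(x, p["lnf_g"], p["lnf_b"])
    logits = h @ p["tok_emb"].T  # weight-tied output projection
    return logits, (ids, caches, c_lnf, h)


def forward(
    ids: "list[int] | np.ndarray", params: TransformerParams, cfg: ModelConfig
) -> np.ndarray:
    """Next-token probability distributions, one row per position.

    Returns an (n, vocab_size) row-stochastic matrix; row i is the model
    distribution of the token following position i given tokens 0..i.
    """
    ids = np.asarray(ids, dtype=int)
    if ids.ndim != 1 or not 1 <= ids.size <= cfg.n_ctx:
        raise ShapeError(
            f"need a 1-D id sequence of length 1..{cfg.n_ctx}, got shape {ids.shape}"
        )
    if ids.min() < 0 or ids.max() >= cfg.vocab_size:
        raise ShapeError("token id out of vocabulary range")
    logits, _ = _forward_batch(ids[None], params, cfg)
    return softmax_tau(logits[0], 1.0, axis=-1)


def loss_and_grads(
    batch: np.ndarray,
    loss_mask: np.ndarray,
    p: TransformerParams,
    cfg: ModelConfig,
):
    """Mean next-token cross-entropy (natural log) over unmasked targets,
    and its gradient for every parameter."""
    logits, (ids, caches, c_lnf, h) = _forward_batch(batch, p, cfg)
    logp = logits - np.max(logits, axis=-1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(-1, keepdims=True))
    targets = batch[:, 1:]
    tmask = loss_mask[:, 1:].astype(float)
    n_pred = tmask.sum()
    picked = np.take_along_axis(logp[:, :-1], targets[..., None], axis=-1)[..., 0]
    loss = -(picked * tmask).sum() / n_pred

    grads = {k: np.zeros_like(v) for k, v in p.items()}
    probs = np.exp(logp)
    dlogits = probs.copy()
    B, n, V = dlogits.shape
    onehot_rows = np.zeros_like(dlogits)
    np.put_along_axis(
        onehot_rows[:, :-1], targets[..., None], 1.0, axis=-1
    )
    dlogits -= onehot_rows
    dlogits[:, :-1] *= tmask[..., None] / n_pred
    dlogits[:, -1] = 0.0  # last position predicts nothing

    grads["tok_emb"] += np.einsum("bnv,bnd->vd", dlogits, h)
    dh = dlogits @ p["tok_emb"]
    dx, dg, db = _ln_bwd(dh, c_lnf)
    grads["lnf_g"] += dg
    grads["lnf_b"] += db
    for i in reversed(range(cfg.n_layers)):
        dx = _block_bwd(dx, caches[i], p, i, cfg, grads)
    # embedding lookups
    np.add.at(grads["tok_emb"], batch.reshape(-1), dx.reshape(-1, cfg.d_model))
    if cfg.positional == "learned":
        grads["pos_emb"][:n] += dx.sum(0)
    return loss, grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _pad_batch(sequences: "list[list[int]]", pad_id: int = 0):
    n = max(len(s) for s in sequences)
    batch = np.full((len(sequences), n), pad_id, dtype=int)
    mask = np.zeros((len(sequences), n), dtype=bool)
    for r, s in enumerate(sequences):
        batch[r, : len(s)] = s
        mask[r, : len(s)] = True
    return batch, mask


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


def train(
    corpus: "list[list[int]]",
    cfg: ModelConfig,
    schedule: TrainSchedule | None = None,
    params: TransformerParams | None = None,
    callback=None,
    prompt_lengths: "list[int] | None" = None,
) -> tuple[TransformerParams, list[float]]:
    """Full-batch gradient training on encoded id sequences.

    Returns the final parameters and the per-step mean cross-entropy trace.
    Identical seeds and corpora give identical traces.

    With ``prompt_lengths`` given (one per sequence), the loss is scored on
    the continuation only — the conditional objective of predicting the
    stem given the label pattern.  Which label follows the first delimiter
    is inherently unpredictable, so full-sequence loss on a multi-label
    corpus has an irreducible floor of roughly ln(n_labels) / sequence
    length; the conditional loss has none and can reach zero on a
    memorizable corpus.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    longest = max(len(s) for s in corpus)
    if longest > cfg.n_ctx:
        raise ShapeError(
            f"longest training sequence ({longest}) exceeds n_ctx={cfg.n_ctx}"
        )
    sched = schedule or TrainSchedule()
    p = params if params is not None else init_params(cfg)
    batch, mask = _pad_batch(corpus)
    if prompt_lengths is not None:
        if len(prompt_lengths) != len(corpus):
            raise ValueError("need one prompt length per sequence")
        for r, plen in enumerate(prompt_lengths):
            mask[r, :plen] = False  # tokens stay visible; loss skips them

    m = {k: np.zeros_like(v) for k, v in p.items()}
    v2 = {k: np.zeros_like(v) for k, v in p.items()}
    b1, b2 = sched.adam_betas
    trace: list[float] = []
    for step in range(1, sched.steps + 1):
        loss, grads = loss_and_grads(batch, mask, p, cfg)
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at step {step}: {loss}")
        trace.append(float(loss))
        for k in p:
            g = grads[k]
            if sched.optimizer == "adam":
                m[k] = b1 * m[k] + (1 - b1) * g
                v2[k] = b2 * v2[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**step)
                vhat = v2[k] / (1 - b2**step)
                p[k] -= sched.lr * mhat / (np.sqrt(vhat) + sched.adam_eps)
            elif sched.optimizer == "momentum":
                m[k] = sched.momentum * m[k] + g
                p[k] -= sched.lr * m[k]
            else:  # plain gradient descent
                p[k] -= sched.lr * g
        if callback and (step % sched.log_every == 0 or step == sched.steps):
            callback(step, float(loss))
    return p, trace


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(
    path: str | Path,
    params: TransformerParams,
    cfg: ModelConfig,
    vocab_ref: str = "",
) -> None:
    """Self-describing archive: version, config, vocab reference, weights."""
    meta = json.dumps(
        {"version": CHECKPOINT_VERSION, "config": asdict(cfg), "vocab": vocab_ref}
    )
    arrays = {"__meta__": np.frombuffer(meta.encode(), dtype=np.uint8)}
    arrays.update(params)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: str | Path) -> tuple[TransformerParams, ModelConfig, str]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"incompatible checkpoint version {meta.get('version')!r}, "
                f"expected {CHECKPOINT_VERSION}"
            )
        cfg = ModelConfig(**meta["config"])
        params = {k: npz[k].copy() for k in npz.files if k != "__meta__"}
    return params, cfg, meta.get("vocab", "")
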