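"""Skip-connected token transformer for tabular ICU LOS regression.

Architecture, in order:

1. batch normalization of the raw standardized input features;
2. ``fzCLSBlock`` — each scalar feature is embedded by its own affine map
   into a d-dimensional token and a trainable, zero-initialized CLS token
   is prepended, giving a (col+1) x d token matrix;
3. one or more ``AttnEncoderBlock``s — multi-head self-attention
   (softmax(QK^T / sqrt(d_k)) V, 5 heads by default) plus a two-layer
   ReLU feed-forward network, each wrapped in residual + layer norm
   (post-norm);
4. the skip-connected token head — the encoder output is batch
   normalized, split into the CLS token (global information) and the
   col feature-wise tokens (local information); the flattened feature
   tokens are projected to a d-vector f, the fused token
   t_sc = Dense(CLS + f) is formed, and a final one-unit dense layer
   predicts the LOS in days.  Ablation modes feed the fusion dense layer
   only the CLS token (``global_only``) or only f (``local_only``).

The CLS token is a directly trainable d-vector at position 0,
zero-initialized — equivalent to embedding a zero scalar through a
trainable bias.  A ``shared_tokenizer`` switch replaces the per-feature
embeddings with a single shared 1->d map.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, layer_norm, softmax

__all__ = [
    "ModelConfig",
    "ModelParams",
    "init_params",
    "embed",
    "attention_encoder",
    "skip_token_head",
    "predict",
    "forward",
    "param_count",
    "save_params",
    "load_params",
]

MODES = ("both", "global_only", "local_only")
BN_EPS = 1e-5
BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class ModelConfig:
    col: int = 16
    d: int = 40
    n_heads: int = 5
    n_blocks: int = 1
    ffn_hidden: int | None = None  # default 4*d
    mode: str = "both"
    shared_tokenizer: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.d % self.n_heads != 0:
            raise ValueError(
                f"embedding dim d={self.d} must be divisible by n_heads={self.n_heads}"
            )
        if self.d < self.n_heads or self.col < 1 or self.n_blocks < 1:
            raise ValueError("degenerate model configuration")

    @property
    def hidden(self) -> int:
        return self.ffn_hidden if self.ffn_hidden is not None else 4 * self.d

    @property
    def d_head(self) -> int:
        return self.d // self.n_heads


class ModelParams:
    """Trainable tensors plus batch-norm running statistics."""

    def __init__(self, config: ModelConfig, weights: dict[str, Tensor], stats: dict[str, np.ndarray]):
        self.config = config
        self.weights = weights
        self.stats = stats

    def __getitem__(self, name: str) -> Tensor:
        return self.weights[name]

    def trainable(self) -> list[Tensor]:
        return list(self.weights.values())

    def zero_grad(self) -> None:
        for t in self.weights.values():
            t.zero_grad()

    def copy(self) -> "ModelParams":
        w = {k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.weights.items()}
        s = {k: v.copy() for k, v in self.stats.items()}
        return ModelParams(self.config, w, s)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: ModelConfig) -> ModelParams:
    """Seed-deterministic Glorot init; CLS vector and biases start at zero;
    batch-norm statistics start at identity (mean 0, var 1)."""
    rng = np.random.default_rng(config.seed)
    c, d, h = config.col, config.d, config.hidden
    w: dict[str, np.ndarray] = {}
    if config.shared_tokenizer:
        w["emb_W"] = _glorot(rng, 1, d, (1, d))
        w["emb_b"] = np.zeros((1, d))
    else:
        w["emb_W"] = _glorot(rng, 1, d, (c, d))
        w["emb_b"] = np.zeros((c, d))
    w["cls"] = np.zeros(d)  # zero-initialized CLS token
    w["bn_in_gamma"] = np.ones(c)
    w["bn_in_beta"] = np.zeros(c)
    for blk in range(config.n_blocks):
        p = f"blk{blk}_"
        for nm in ("Wq", "Wk", "Wv", "Wo"):
            w[p + nm] = _glorot(rng, d, d, (d, d))
            w[p + nm.lower().replace("w", "b")] = np.zeros(d)
        w[p + "ffn_W1"] = _glorot(rng, d, h, (d, h))
        w[p + "ffn_b1"] = np.zeros(h)
        w[p + "ffn_W2"] = _glorot(rng, h, d, (h, d))
        w[p + "ffn_b2"] = np.zeros(d)
        w[p + "ln1_g"] = np.ones(d)
        w[p + "ln1_b"] = np.zeros(d)
        w[p + "ln2_g"] = np.ones(d)
        w[p + "ln2_b"] = np.zeros(d)
    nchan = (c + 1) * d
    w["bn_out_gamma"] = np.ones(nchan)
    w["bn_out_beta"] = np.zeros(nchan)
    w["fuse_f_W"] = _glorot(rng, c * d, d, (c * d, d))
    w["fuse_f_b"] = np.zeros(d)
    w["fuse_t_W"] = _glorot(rng, d, d, (d, d))
    w["fuse_t_b"] = np.zeros(d)
    w["head_W"] = _glorot(rng, d, 1, (d, 1))
    w["head_b"] = np.zeros(1)
    weights = {k: Tensor(v, requires_grad=True) for k, v in w.items()}
    stats = {
        "bn_in_mean": np.zeros(c),
        "bn_in_var": np.ones(c),
        "bn_out_mean": np.zeros(nchan),
        "bn_out_var": np.ones(nchan),
    }
    return ModelParams(config, weights, stats)


def param_count(config: ModelConfig) -> int:
    """Closed-form trainable-parameter count for a configuration."""
    c, d, h = config.col, config.d, config.hidden
    emb = (1 if config.shared_tokenizer else c) * d * 2
    cls = d
    bn_in = 2 * c
    per_block = 4 * (d * d + d) + (d * h + h) + (h * d + d) + 4 * d
    bn_out = 2 * (c + 1) * d
    head = (c * d * d + d) + (d * d + d) + (d + 1)
    return emb + cls + bn_in + per_block * config.n_blocks + bn_out + head


# ---------------------------------------------------------------------------
# Forward passes (Tensor in, Tensor out; ndarray wrappers at the end)


def _batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    stats: dict,
    key: str,
    train: bool,
) -> Tensor:
    """BatchNorm over axis 0; updates running stats in training mode."""
    if train:
        if x.shape[0] < 2:
            raise ValueError("batch norm in training mode needs batch size >= 2")
        mu = x.mean(axis=0, keepdims=True)
        centered = x - mu
        var = centered.pow(2.0).mean(axis=0, keepdims=True)
        m = BN_MOMENTUM
        stats[key + "_mean"] = m * stats[key + "_mean"] + (1 - m) * mu.data[0]
        stats[key + "_var"] = m * stats[key + "_var"] + (1 - m) * var.data[0]
        return centered * (var + BN_EPS).pow(-0.5) * gamma + beta
    mu = stats[key + "_mean"]
    sd = np.sqrt(stats[key + "_var"] + BN_EPS)
    return (x + Tensor(-mu)) * Tensor(1.0 / sd) * gamma + beta


def embed(x: Tensor, params: ModelParams) -> Tensor:
    """fzCLSBlock: (B, col) scalars -> (B, col+1, d) tokens, CLS at row 0."""
    cfg = params.config
    B = x.shape[0]
    if x.shape[1] != cfg.col:
        raise ValueError(f"expected {cfg.col} features, got {x.shape[1]}")
    xc = x.reshape(B, cfg.col, 1)
    W = params["emb_W"].reshape(1, -1, cfg.d)
    b = params["emb_b"].reshape(1, -1, cfg.d)
    tokens = xc * W + b  # shared tokenizer broadcasts its single row
    cls = params["cls"].reshape(1, 1, cfg.d) * Tensor(np.ones((B, 1, 1)))
    from .autodiff import concat

    return concat([cls, tokens], axis=1)


def attention_encoder(tokens: Tensor, params: ModelParams, block: int = 0) -> Tensor:
    """One AttnEncoderBlock: multi-head self-attention + FFN (post-norm)."""
    cfg = params.config
    p = f"blk{block}_"
    B, T, d = tokens.shape
    H, dk = cfg.n_heads, cfg.d_head

    def split_heads(t: Tensor) -> Tensor:
        return t.reshape(B, T, H, dk).transpose(0, 2, 1, 3)  # (B,H,T,dk)

    q = split_heads(tokens @ params[p + "Wq"] + params[p + "bq"])
    k = split_heads(tokens @ params[p + "Wk"] + params[p + "bk"])
    v = split_heads(tokens @ params[p + "Wv"] + params[p + "bv"])
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
    attn = softmax(scores, axis=-1)
    heads = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
    msa = heads @ params[p + "Wo"] + params[p + "bo"]
    h = layer_norm(tokens + msa, params[p + "ln1_g"], params[p + "ln1_b"])
    ffn = (h @ params[p + "ffn_W1"] + params[p + "ffn_b1"]).relu() @ params[
        p + "ffn_W2"
    ] + params[p + "ffn_b2"]
    return layer_norm(h + ffn, params[p + "ln2_g"], params[p + "ln2_b"])


def attention_weights(tokens: np.ndarray, params: ModelParams, block: int = 0) -> np.ndarray:
    """(B, heads, T, T) softmax attention maps (diagnostic helper)."""
    cfg = params.config
    p = f"blk{block}_"
    t = Tensor(tokens)
    B, T, d = t.shape
    H, dk = cfg.n_heads, cfg.d_head

    def sh(x):
        return x.reshape(B, T, H, dk).transpose(0, 2, 1, 3)

    q = sh(t @ params[p + "Wq"] + params[p + "bq"])
    k = sh(t @ params[p + "Wk"] + params[p + "bk"])
    return softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk)), axis=-1).data


def skip_token_head(
    tokens: Tensor, params: ModelParams, mode: str | None = None, train: bool = False
) -> Tensor:
    """Fusion head on encoded tokens -> (B,) prediction in days.

    Applies the post-encoder batch normalization internally (each of the
    (col+1)*d activations is one channel), splits CLS from the feature
    tokens, projects the flattened feature tokens to f, and feeds
    CLS + f (or one of them, per ablation mode) through the fused dense
    layer and the one-unit output layer.
    """
    cfg = params.config
    mode = mode or cfg.mode
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    B, T, d = tokens.shape
    flat = tokens.reshape(B, T * d)
    flat = _batch_norm(
        flat, params["bn_out_gamma"], params["bn_out_beta"], params.stats, "bn_out", train
    )
    cls = flat[:, :d]
    f_prime = flat[:, d:]
    f = f_prime @ params["fuse_f_W"] + params["fuse_f_b"]
    if mode == "both":
        fused = cls + f
    elif mode == "global_only":
        fused = cls
    else:
        fused = f
    t_sc = fused @ params["fuse_t_W"] + params["fuse_t_b"]
    out = t_sc @ params["head_W"] + params["head_b"]
    return out.reshape(B)


def forward(
    x: Tensor, params: ModelParams, mode: str | None = None, train: bool = False
) -> Tensor:
    """Full differentiable forward pass: (B, col) -> (B,) days."""
    cfg = params.config
    x = _batch_norm(
        x, params["bn_in_gamma"], params["bn_in_beta"], params.stats, "bn_in", train
    )
    tokens = embed(x, params)
    for blk in range(cfg.n_blocks):
        tokens = attention_encoder(tokens, params, blk)
    return skip_token_head(tokens, params, mode=mode, train=train)


def predict(
    x_batch: np.ndarray, params: ModelParams, mode: str | None = None
) -> np.ndarray:
    """Evaluation-mode predictions (running BN statistics; batch-independent)."""
    x = np.atleast_2d(np.asarray(x_batch, dtype=float))
    if x.shape[1] != params.config.col:
        raise ValueError(
            f"expected {params.config.col} feature columns, got {x.shape[1]}"
        )
    return forward(Tensor(x), params, mode=mode, train=False).data


# ---------------------------------------------------------------------------
# Checkpointing

CHECKPOINT_VERSION = 1


def save_params(params: ModelParams, path) -> None:
    """Single portable checkpoint: weights + BN stats + embedded config."""
    arrays = {f"w::{k}": v.data for k, v in params.weights.items()}
    arrays.update({f"s::{k}": v for k, v in params.stats.items()})
    meta = json.dumps(
        {"version": CHECKPOINT_VERSION, "config": asdict(params.config)}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_params(path) -> ModelParams:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        config = ModelConfig(**meta["config"])
        weights = {
            k[3:]: Tensor(npz[k], requires_grad=True)
            for k in npz.files
            if k.startswith("w::")
        }
        stats = {k[3:]: npz[k].copy() for k in npz.files if k.startswith("s::")}
    return ModelParams(config, weights, stats)
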