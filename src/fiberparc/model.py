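"""The streamline-token transformer: tokenization, encoder, classifier head.

Each resampled streamline (n_points x 3 coordinates in [-1, 1]) is one
token; self-attention over the subtractogram lets streamlines serve as
global context for one another. There is no positional encoding on either
axis: the context axis must stay permutation-equivariant (streamline order
is meaningless), and the point axis is flattened into the token itself.

The network is implemented directly in NumPy (float32), with explicit
forward caching and hand-derived backward passes for every sublayer, so
training and inference run on any CPU with no deep-learning framework.

Tokenization reads the flattened 3*n_points coordinates into the first
entries of the token and fills the remaining d_model - 3*n_points entries
with a learned bias-free linear map of those same coordinates
(``token_mode='pad_linear'``, the default). A full learned projection to
d_model is available as ``token_mode='projection'`` for sensitivity
checks.

Encoder sublayers are post-norm: residual add, then layer normalization;
dropout acts on each sublayer output and is active only in train mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .preprocess import Subtractogram

__all__ = [
    "ModelConfig",
    "StreamlineTransformer",
    "count_parameters",
    "cross_entropy",
    "save_checkpoint",
    "load_checkpoint",
]

_CHECKPOINT_VERSION = "fiberparc-ckpt-1"
_LN_EPS = 1e-5


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale configuration: 8 encoder layers of
    single-head self-attention with a 256-unit feed-forward network,
    token width 128, dropout 0.1, a 256-unit classification block, and
    1600 output units (one per streamline cluster), on 15-point
    streamlines.
    """

    d_model: int = 128
    n_layers: int = 8
    n_heads: int = 1
    ffn_hidden: int = 256
    dropout: float = 0.1
    clf_hidden: int = 256
    n_classes: int = 1600
    n_points: int = 15
    token_mode: str = "pad_linear"

    def __post_init__(self):
        if self.token_mode not in ("pad_linear", "projection"):
            raise ValueError("token_mode must be 'pad_linear' or 'projection'")
        if self.token_mode == "pad_linear" and 3 * self.n_points > self.d_model:
            raise ValueError("pad_linear tokenization needs 3*n_points <= d_model")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def n_coords(self) -> int:
        return 3 * self.n_points


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)


def _linear_fwd(x, w, b=None):
    y = x @ w
    if b is not None:
        y = y + b
    return y


def _linear_bwd(dy, x, w):
    axes = tuple(range(x.ndim - 1))
    dw = np.tensordot(x, dy, axes=(axes, axes))
    db = dy.sum(axis=axes)
    dx = dy @ w.T
    return dx, dw.astype(np.float32), db.astype(np.float32)


def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv)


def _layernorm_bwd(dy, g, cache):
    xhat, inv = cache
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    axes = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=axes).astype(np.float32)
    db = dy.sum(axis=axes).astype(np.float32)
    return dx, dg, db


def _softmax(x):
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean per-token cross-entropy and its gradient w.r.t. the logits.

    logits: (B, N, C); labels: (B, N) integer class ids.
    """
    b, n, c = logits.shape
    shifted = logits - logits.max(axis=-1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    logp = shifted - logz
    idx = (np.arange(b)[:, None], np.arange(n)[None, :], labels)
    loss = -logp[idx].mean()
    dlogits = np.exp(logp)
    dlogits[idx] -= 1.0
    dlogits /= b * n
    return float(loss), dlogits.astype(np.float32)


class StreamlineTransformer:
    """Permutation-equivariant per-streamline classifier.

    Parameters are float32 arrays in a flat dict; the forward pass accepts
    any context size N >= 1 with one set of weights.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0,
                 params: Optional[dict] = None):
        self.cfg = cfg
        self.params = params if params is not None else self._init_params(seed)

    # ---- parameters -----------------------------------------------------

    def _init_params(self, seed: int) -> dict:
        cfg = self.cfg
        rng = np.random.default_rng(seed)
        p = {}
        f, d = cfg.n_coords, cfg.d_model
        if cfg.token_mode == "pad_linear":
            p["tok.Wpad"] = _glorot(rng, f, d - f)
        else:
            p["tok.Wproj"] = _glorot(rng, f, d)
            p["tok.bproj"] = np.zeros(d, dtype=np.float32)
        for l in range(cfg.n_layers):
            pre = f"layers.{l}."
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[pre + name] = _glorot(rng, d, d)
                p[pre + name.replace("W", "b")] = np.zeros(d, dtype=np.float32)
            p[pre + "ln1.g"] = np.ones(d, dtype=np.float32)
            p[pre + "ln1.b"] = np.zeros(d, dtype=np.float32)
            p[pre + "W1"] = _glorot(rng, d, cfg.ffn_hidden)
            p[pre + "b1"] = np.zeros(cfg.ffn_hidden, dtype=np.float32)
            p[pre + "W2"] = _glorot(rng, cfg.ffn_hidden, d)
            p[pre + "b2"] = np.zeros(d, dtype=np.float32)
            p[pre + "ln2.g"] = np.ones(d, dtype=np.float32)
            p[pre + "ln2.b"] = np.zeros(d, dtype=np.float32)
        p["head.Wh"] = _glorot(rng, d, cfg.clf_hidden)
        p["head.bh"] = np.zeros(cfg.clf_hidden, dtype=np.float32)
        p["head.Wc"] = _glorot(rng, cfg.clf_hidden, cfg.n_classes)
        p["head.bc"] = np.zeros(cfg.n_classes, dtype=np.float32)
        return p

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def copy(self) -> "StreamlineTransformer":
        return StreamlineTransformer(
            self.cfg, params={k: v.copy() for k, v in self.params.items()}
        )

    # ---- forward --------------------------------------------------------

    @staticmethod
    def _coerce(x) -> np.ndarray:
        if isinstance(x, Subtractogram):
            x = x.streamlines
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:  # (N, P, 3) -> batch of one
            x = x[None]
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError("expected coordinates of shape (B, N, n_points, 3)")
        return x

    def tokenize(self, x) -> np.ndarray:
        """Map (B, N, n_points, 3) coordinates to (B, N, d_model) tokens.

        In pad_linear mode the first 3*n_points token entries are the
        flattened coordinates verbatim; the rest are a learned bias-free
        linear function of them.
        """
        x = self._coerce(x)
        cfg = self.cfg
        if x.shape[2] != cfg.n_points:
            raise ValueError(
                f"streamlines have {x.shape[2]} points, model expects {cfg.n_points}"
            )
        flat = x.reshape(x.shape[0], x.shape[1], cfg.n_coords)
        if cfg.token_mode == "pad_linear":
            pad = flat @ self.params["tok.Wpad"]
            return np.concatenate([flat, pad], axis=-1)
        return _linear_fwd(flat, self.params["tok.Wproj"], self.params["tok.bproj"])

    def _split_heads(self, x):
        b, n, d = x.shape
        h = self.cfg.n_heads
        return x.reshape(b, n, h, d // h).transpose(0, 2, 1, 3)

    def _merge_heads(self, x):
        b, h, n, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, n, h * dk)

    def _dropout_mask(self, shape, train, rng):
        p = self.cfg.dropout
        if not train or p == 0.0:
            return None
        if rng is None:
            raise ValueError("train-mode forward needs an rng for dropout")
        return (rng.random(shape) >= p).astype(np.float32) / (1.0 - p)

    def forward(self, x, train: bool = False, rng=None, return_cache: bool = False):
        """Full forward pass: tokenize -> encode -> classify.

        Returns per-streamline logits of shape (B, N, n_classes); with
        ``return_cache=True`` also the cache needed by :meth:`backward`.
        """
        x = self._coerce(x)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite coordinates in model input")
        p, cfg = self.params, self.cfg
        flat = x.reshape(x.shape[0], x.shape[1], cfg.n_coords)
        if cfg.token_mode == "pad_linear":
            tok = np.concatenate([flat, flat @ p["tok.Wpad"]], axis=-1)
        else:
            tok = _linear_fwd(flat, p["tok.Wproj"], p["tok.bproj"])
        cache = {"flat": flat, "layers": []}
        h = tok
        scale = 1.0 / np.sqrt(cfg.d_model // cfg.n_heads)
        for l in range(cfg.n_layers):
            pre = f"layers.{l}."
            q = _linear_fwd(h, p[pre + "Wq"], p[pre + "bq"])
            k = _linear_fwd(h, p[pre + "Wk"], p[pre + "bk"])
            v = _linear_fwd(h, p[pre + "Wv"], p[pre + "bv"])
            qh, kh, vh = map(self._split_heads, (q, k, v))
            scores = (qh @ kh.transpose(0, 1, 3, 2)) * scale
            attn = _softmax(scores)
            ctx = self._merge_heads(attn @ vh)
            out = _linear_fwd(ctx, p[pre + "Wo"], p[pre + "bo"])
            mask_a = self._dropout_mask(out.shape, train, rng)
            if mask_a is not None:
                out = out * mask_a
            r1 = h + out
            h1, ln1_cache = _layernorm_fwd(r1, p[pre + "ln1.g"], p[pre + "ln1.b"])
            u = _linear_fwd(h1, p[pre + "W1"], p[pre + "b1"])
            relu_u = np.maximum(u, 0.0)
            ff = _linear_fwd(relu_u, p[pre + "W2"], p[pre + "b2"])
            mask_f = self._dropout_mask(ff.shape, train, rng)
            if mask_f is not None:
                ff = ff * mask_f
            r2 = h1 + ff
            h2, ln2_cache = _layernorm_fwd(r2, p[pre + "ln2.g"], p[pre + "ln2.b"])
            cache["layers"].append(
                dict(h=h, qh=qh, kh=kh, vh=vh, attn=attn, ctx=ctx,
                     mask_a=mask_a, ln1=ln1_cache, h1=h1, u=u, relu_u=relu_u,
                     mask_f=mask_f, ln2=ln2_cache)
            )
            h = h2
        z = _linear_fwd(h, p["head.Wh"], p["head.bh"])
        relu_z = np.maximum(z, 0.0)
        logits = _linear_fwd(relu_z, p["head.Wc"], p["head.bc"])
        cache.update(encoded=h, z=z, relu_z=relu_z)
        if return_cache:
            return logits, cache
        return logits

    def encode(self, tokens_or_coords, train: bool = False, rng=None) -> np.ndarray:
        """Encoder output (B, N, d_model) for normalized coordinates."""
        _, cache = self.forward(tokens_or_coords, train=train, rng=rng,
                                return_cache=True)
        return cache["encoded"]

    def classify(self, encoded: np.ndarray) -> np.ndarray:
        """Tokenwise two-layer head (linear -> ReLU -> linear) on encoder output."""
        p = self.params
        z = np.maximum(_linear_fwd(encoded, p["head.Wh"], p["head.bh"]), 0.0)
        return _linear_fwd(z, p["head.Wc"], p["head.bc"])

    # ---- backward -------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict:
        """Gradient of the loss w.r.t. every parameter, given dL/dlogits."""
        p, cfg = self.params, self.cfg
        grads = {}
        scale = 1.0 / np.sqrt(cfg.d_model // cfg.n_heads)
        drelu_z, grads["head.Wc"], grads["head.bc"] = _linear_bwd(
            dlogits, cache["relu_z"], p["head.Wc"]
        )
        dz = drelu_z * (cache["z"] > 0)
        dh, grads["head.Wh"], grads["head.bh"] = _linear_bwd(
            dz, cache["encoded"], p["head.Wh"]
        )
        for l in reversed(range(cfg.n_layers)):
            pre = f"layers.{l}."
            c = cache["layers"][l]
            dr2, grads[pre + "ln2.g"], grads[pre + "ln2.b"] = _layernorm_bwd(
                dh, p[pre + "ln2.g"], c["ln2"]
            )
            dff = dr2.copy()
            if c["mask_f"] is not None:
                dff = dff * c["mask_f"]
            drelu_u, grads[pre + "W2"], grads[pre + "b2"] = _linear_bwd(
                dff, c["relu_u"], p[pre + "W2"]
            )
            du = drelu_u * (c["u"] > 0)
            dh1_ffn, grads[pre + "W1"], grads[pre + "b1"] = _linear_bwd(
                du, c["h1"], p[pre + "W1"]
            )
            dh1 = dr2 + dh1_ffn
            dr1, grads[pre + "ln1.g"], grads[pre + "ln1.b"] = _layernorm_bwd(
                dh1, p[pre + "ln1.g"], c["ln1"]
            )
            dout = dr1.copy()
            if c["mask_a"] is not None:
                dout = dout * c["mask_a"]
            dctx, grads[pre + "Wo"], grads[pre + "bo"] = _linear_bwd(
                dout, c["ctx"], p[pre + "Wo"]
            )
            dctx_h = self._split_heads(dctx)
            dattn = dctx_h @ c["vh"].transpose(0, 1, 3, 2)
            dvh = c["attn"].transpose(0, 1, 3, 2) @ dctx_h
            a = c["attn"]
            dscores = a * (dattn - (dattn * a).sum(axis=-1, keepdims=True))
            dqh = (dscores @ c["kh"]) * scale
            dkh = (dscores.transpose(0, 1, 3, 2) @ c["qh"]) * scale
            dq, dk, dv = map(self._merge_heads, (dqh, dkh, dvh))
            dh_q, grads[pre + "Wq"], grads[pre + "bq"] = _linear_bwd(
                dq, c["h"], p[pre + "Wq"]
            )
            dh_k, grads[pre + "Wk"], grads[pre + "bk"] = _linear_bwd(
                dk, c["h"], p[pre + "Wk"]
            )
            dh_v, grads[pre + "Wv"], grads[pre + "bv"] = _linear_bwd(
                dv, c["h"], p[pre + "Wv"]
            )
            dh = dr1 + dh_q + dh_k + dh_v
        flat = cache["flat"]
        if cfg.token_mode == "pad_linear":
            f = cfg.n_coords
            axes = tuple(range(flat.ndim - 1))
            grads["tok.Wpad"] = np.tensordot(
                flat, dh[..., f:], axes=(axes, axes)
            ).astype(np.float32)
        else:
            _, grads["tok.Wproj"], grads["tok.bproj"] = _linear_bwd(
                dh, flat, p["tok.Wproj"]
            )
        return grads

    # ---- convenience ----------------------------------------------------

    def predict_logits(self, sub) -> np.ndarray:
        """Eval-mode logits (N, n_classes) for one subtractogram."""
        return self.forward(sub, train=False)[0]

    def predict_labels(self, sub) -> np.ndarray:
        """Eval-mode argmax cluster ids (N,) for one subtractogram."""
        return self.predict_logits(sub).argmax(axis=-1)


def count_parameters(cfg: ModelConfig) -> int:
    """Closed-form parameter count; matches the instantiated model exactly."""
    f, d = cfg.n_coords, cfg.d_model
    if cfg.token_mode == "pad_linear":
        n = f * (d - f)
    else:
        n = f * d + d
    per_layer = (
        4 * (d * d + d)          # Q, K, V, output projections
        + 2 * d                  # ln1
        + d * cfg.ffn_hidden + cfg.ffn_hidden
        + cfg.ffn_hidden * d + d
        + 2 * d                  # ln2
    )
    n += cfg.n_layers * per_layer
    n += d * cfg.clf_hidden + cfg.clf_hidden
    n += cfg.clf_hidden * cfg.n_classes + cfg.n_classes
    return n


def save_checkpoint(path, model: StreamlineTransformer,
                    class_ids: Optional[np.ndarray] = None,
                    extra: Optional[dict] = None) -> None:
    """Serialize model weights + config (+ output-class id ordering) to .npz."""
    header = {
        "version": _CHECKPOINT_VERSION,
        "config": asdict(model.cfg),
        "extra": extra or {},
    }
    arrays = {"param." + k: v for k, v in model.params.items()}
    if class_ids is not None:
        arrays["class_ids"] = np.asarray(class_ids, dtype=np.int64)
    np.savez(path, header=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns (model, class_ids or None, header dict)."""
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        if header.get("version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version in {path!r}")
        params = {k[len("param."):]: z[k].astype(np.float32)
                  for k in z.files if k.startswith("param.")}
        class_ids = z["class_ids"] if "class_ids" in z.files else None
    cfg = ModelConfig(**header["config"])
    return StreamlineTransformer(cfg, params=params), class_ids, header
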