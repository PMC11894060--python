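"""Pharmacophore-conditioned autoregressive SMILES decoder.

A small GPT-style transformer decoder implemented in NumPy, trained to
predict the next SMILES token given a pharmacophore condition channel.
The condition (a binary fingerprint or an 8-long feature-count vector) is
laid out as a prefix of learned value embeddings before the begin token;
segment embeddings (0 for condition positions, 1 for SMILES positions)
distinguish the two channels, and rotary positional encoding is applied to
queries and keys inside every causal multi-head attention block.

The loss is next-token cross-entropy evaluated on SMILES positions only:
condition positions are never predicted, and padding after the
end-of-sequence token is masked out.

Everything (initialization, minibatch order, dropout) is driven by the
config seed, so identical (corpus, config) pairs train to identical
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ModelConfig",
    "DecoderState",
    "apply_rotary",
    "init_params",
    "forward",
    "loss_and_grads",
    "train",
    "condition_length",
    "save_state",
    "load_state",
]

COUNT_CLIP = 15  # feature counts are clipped here to bound the embedding table

CONDITION_KINDS = {
    "fingerprint_72": (72, 2),
    "fingerprint_108": (108, 2),
    "fingerprint_1032": (1032, 2),
    "counts_8": (8, COUNT_CLIP + 1),
    "none": (0, 0),
}


@dataclass
class ModelConfig:
    """Hyperparameters of the decoder.

    ``embed_dim`` must be divisible by ``2 * n_heads`` so every head gets an
    even number of dimensions to pair up for the rotary encoding.
    """

    vocab_size: int
    n_layers: int = 2
    n_heads: int = 4
    embed_dim: int = 128
    feedforward_dim: int = 512
    max_seq_len: int = 256
    rope_theta: float = 10000.0
    condition_kind: str = "fingerprint_72"
    dropout: float = 0.0
    seed: int = 0
    attention: str = "softmax"
    dtype: str = "float32"

    def __post_init__(self):
        if self.condition_kind not in CONDITION_KINDS:
            raise ValueError(f"unknown condition_kind {self.condition_kind!r}")
        if self.embed_dim % (2 * self.n_heads) != 0:
            raise ValueError("embed_dim must be divisible by 2 * n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.attention != "softmax":
            raise ValueError("only softmax attention is implemented")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @property
    def cond_len(self) -> int:
        return CONDITION_KINDS[self.condition_kind][0]

    @property
    def cond_values(self) -> int:
        return CONDITION_KINDS[self.condition_kind][1]


def condition_length(kind: str) -> int:
    return CONDITION_KINDS[kind][0]


@dataclass
class DecoderState:
    """Trained parameters plus everything needed to reuse them safely."""

    params: dict
    config: ModelConfig
    vocab_hash: str
    loss_history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# rotary positional encoding


def _rope_angles(positions: np.ndarray, dim: int, theta: float) -> np.ndarray:
    """Angles (len(positions), dim/2): position * theta^(-2i/dim)."""
    inv_freq = theta ** (-np.arange(0, dim, 2, dtype=np.float64) / dim)
    return np.asarray(positions, dtype=np.float64)[..., None] * inv_freq


def apply_rotary(vec: np.ndarray, position, theta: float = 10000.0) -> np.ndarray:
    """Rotate consecutive dimension pairs (2i, 2i+1) of *vec* by the angle
    position * theta^(-2i/d).  Norm-preserving; position 0 is the identity.

    ``vec`` may be a single d-vector or a (..., d) array with matching
    broadcastable ``position``.
    """
    vec = np.asarray(vec, dtype=np.float64)
    d = vec.shape[-1]
    if d % 2:
        raise ValueError("rotary encoding requires an even dimension")
    ang = _rope_angles(np.asarray(position), d, theta)
    cos, sin = np.cos(ang), np.sin(ang)
    x = vec[..., 0::2]
    y = vec[..., 1::2]
    out = np.empty_like(vec)
    out[..., 0::2] = x * cos - y * sin
    out[..., 1::2] = x * sin + y * cos
    return out


def _rope_tables(L: int, head_dim: int, theta: float):
    ang = _rope_angles(np.arange(L), head_dim, theta)  # (L, hd/2)
    return np.cos(ang), np.sin(ang)


def _rot(x, cos, sin):
    # x: (B, H, L, hd); cos/sin: (L, hd/2)
    a = x[..., 0::2]
    b = x[..., 1::2]
    out = np.empty_like(x)
    out[..., 0::2] = a * cos - b * sin
    out[..., 1::2] = a * sin + b * cos
    return out


def _rot_back(g, cos, sin):
    # transpose of the rotation: rotate gradients by the negative angle
    a = g[..., 0::2]
    b = g[..., 1::2]
    out = np.empty_like(g)
    out[..., 0::2] = a * cos + b * sin
    out[..., 1::2] = -a * sin + b * cos
    return out


# ---------------------------------------------------------------------------
# parameter initialization


def init_params(config: ModelConfig) -> dict:
    """Seeded Gaussian init (scaled residual projections, zero biases)."""
    rng = np.random.default_rng(config.seed)
    d, f, V = config.embed_dim, config.feedforward_dim, config.vocab_size
    dt = np.dtype(config.dtype)
    std = 0.02
    res_std = std / np.sqrt(2.0 * config.n_layers)

    def g(*shape, s=std):
        return rng.normal(0.0, s, size=shape).astype(dt)

    p = {
        "tok_emb": g(V, d),
        "seg_emb": g(2, d),
        "lnf_g": np.ones(d, dtype=dt),
        "lnf_b": np.zeros(d, dtype=dt),
        "W_out": g(d, V),
        "b_out": np.zeros(V, dtype=dt),
    }
    if config.cond_len:
        p["cond_val_emb"] = g(config.cond_values, d)
        p["cond_pos_emb"] = g(config.cond_len, d)
    for l in range(config.n_layers):
        p.update(
            {
                f"l{l}.ln1_g": np.ones(d, dtype=dt),
                f"l{l}.ln1_b": np.zeros(d, dtype=dt),
                f"l{l}.Wq": g(d, d),
                f"l{l}.bq": np.zeros(d, dtype=dt),
                f"l{l}.Wk": g(d, d),
                f"l{l}.bk": np.zeros(d, dtype=dt),
                f"l{l}.Wv": g(d, d),
                f"l{l}.bv": np.zeros(d, dtype=dt),
                f"l{l}.Wo": g(d, d, s=res_std),
                f"l{l}.bo": np.zeros(d, dtype=dt),
                f"l{l}.ln2_g": np.ones(d, dtype=dt),
                f"l{l}.ln2_b": np.zeros(d, dtype=dt),
                f"l{l}.W1": g(d, f),
                f"l{l}.b1": np.zeros(f, dtype=dt),
                f"l{l}.W2": g(f, d, s=res_std),
                f"l{l}.b2": np.zeros(d, dtype=dt),
            }
        )
    return p


# ---------------------------------------------------------------------------
# forward / backward primitives

_LN_EPS = 1e-5


def _layernorm_fwd(x, gamma, beta):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return xhat * gamma + beta, (xhat, inv, gamma)


def _layernorm_bwd(dy, cache):
    xhat, inv, gamma = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * gamma
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


_GELU_C = float(np.sqrt(2.0 / np.pi))


def _gelu_fwd(x):
    u = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(u)
    return 0.5 * x * (1.0 + t), (x, t)


def _gelu_bwd(dy, cache):
    x, t = cache
    du = _GELU_C * (1.0 + 3 * 0.044715 * x**2)
    return dy * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du)


def _softmax(z):
    z = z - z.max(-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(-1, keepdims=True)


# ---------------------------------------------------------------------------
# forward pass


def _embed(params, config: ModelConfig, cond, ids, segment=None):
    """Build the input embedding matrix (B, C+T, d) and segment ids."""
    B, T = ids.shape
    C = config.cond_len
    L = C + T
    if L > config.max_seq_len:
        raise ValueError(f"sequence length {L} exceeds max_seq_len {config.max_seq_len}")
    if segment is None:
        segment = np.concatenate(
            [np.zeros((B, C), dtype=np.int64), np.ones((B, T), dtype=np.int64)], axis=1
        )
    parts = []
    if C:
        if cond is None:
            raise ValueError(f"condition_kind {config.condition_kind} requires a condition")
        cond = np.asarray(cond, dtype=np.int64)
        if cond.shape != (B, C):
            raise ValueError(f"condition shape {cond.shape} != {(B, C)}")
        cond = np.clip(cond, 0, config.cond_values - 1)
        parts.append(params["cond_val_emb"][cond] + params["cond_pos_emb"][None, :, :])
    parts.append(params["tok_emb"][ids])
    x = np.concatenate(parts, axis=1) if len(parts) > 1 else parts[0]
    x = x + params["seg_emb"][segment]
    return x, segment, cond


def forward(params, config: ModelConfig, cond, ids, segment=None, want_cache=False,
            dropout_rng=None):
    """Run the decoder; returns logits (B, C+T, V) (and caches if asked).

    Causality holds over the whole sequence: the output at any position
    depends only on the condition prefix and tokens at or before it.
    """
    x, segment, cond = _embed(params, config, cond, ids, segment)
    B, L, d = x.shape
    H, hd = config.n_heads, config.head_dim
    cos, sin = _rope_tables(L, hd, config.rope_theta)
    cos = cos.astype(x.dtype)
    sin = sin.astype(x.dtype)
    causal = np.triu(np.full((L, L), -np.inf, dtype=x.dtype), k=1)
    keep = 1.0 - config.dropout
    caches = {"embed": (cond, ids, segment, B, L)}
    for l in range(config.n_layers):
        h, ln1c = _layernorm_fwd(x, params[f"l{l}.ln1_g"], params[f"l{l}.ln1_b"])
        q = h @ params[f"l{l}.Wq"] + params[f"l{l}.bq"]
        k = h @ params[f"l{l}.Wk"] + params[f"l{l}.bk"]
        v = h @ params[f"l{l}.Wv"] + params[f"l{l}.bv"]
        qh = q.reshape(B, L, H, hd).transpose(0, 2, 1, 3)
        kh = k.reshape(B, L, H, hd).transpose(0, 2, 1, 3)
        vh = v.reshape(B, L, H, hd).transpose(0, 2, 1, 3)
        qr = _rot(qh, cos, sin)
        kr = _rot(kh, cos, sin)
        scores = qr @ kr.transpose(0, 1, 3, 2) * (1.0 / hd**0.5) + causal
        attn = _softmax(scores)
        ctx = attn @ vh
        ctx2 = ctx.transpose(0, 2, 1, 3).reshape(B, L, d)
        proj = ctx2 @ params[f"l{l}.Wo"] + params[f"l{l}.bo"]
        if dropout_rng is not None and config.dropout > 0:
            m1 = (dropout_rng.random(proj.shape) < keep) / keep
            proj = proj * m1
        else:
            m1 = None
        x = x + proj
        h2, ln2c = _layernorm_fwd(x, params[f"l{l}.ln2_g"], params[f"l{l}.ln2_b"])
        z1 = h2 @ params[f"l{l}.W1"] + params[f"l{l}.b1"]
        a1, gc = _gelu_fwd(z1)
        z2 = a1 @ params[f"l{l}.W2"] + params[f"l{l}.b2"]
        if dropout_rng is not None and config.dropout > 0:
            m2 = (dropout_rng.random(z2.shape) < keep) / keep
            z2 = z2 * m2
        else:
            m2 = None
        x = x + z2
        if want_cache:
            caches[l] = (h, ln1c, qr, kr, vh, attn, ctx2, h2, ln2c, gc, a1, m1, m2)
    xf, lnfc = _layernorm_fwd(x, params["lnf_g"], params["lnf_b"])
    logits = xf @ params["W_out"] + params["b_out"]
    if want_cache:
        caches["final"] = (xf, lnfc)
        caches["rope"] = (cos, sin)
        return logits, caches
    return logits


def next_token_probs(params, config: ModelConfig, cond, ids, temperature: float = 1.0):
    """Probability distribution over the vocabulary for the next token of
    each sequence in the batch (softmax of the last position's logits)."""
    logits = forward(params, config, cond, ids)
    return _softmax(logits[:, -1, :] / temperature)


# ---------------------------------------------------------------------------
# loss and gradients


def loss_and_grads(params, config: ModelConfig, cond, ids, loss_mask,
                   segment=None, dropout_rng=None):
    """Masked next-token cross-entropy and its parameter gradients.

    ``loss_mask`` has shape (B, T) aligned with ``ids``: mask[b, t] = 1
    means the token ids[b, t] is a prediction target (t >= 1; targets on
    condition positions are impossible by construction).
    """
    logits, caches = forward(params, config, cond, ids, segment, want_cache=True,
                             dropout_rng=dropout_rng)
    cond_arr, ids, segment, B, L = caches["embed"]
    C = config.cond_len
    T = ids.shape[1]
    probs = _softmax(logits)

    dt = probs.dtype
    mask = np.asarray(loss_mask, dtype=dt)
    if mask.shape != ids.shape:
        raise ValueError("loss_mask must align with token ids")
    # position C + t - 1 predicts ids[:, t]
    full_mask = np.zeros((B, L), dtype=dt)
    full_mask[:, C : C + T - 1] = mask[:, 1:]
    targets = np.zeros((B, L), dtype=np.int64)
    targets[:, C : C + T - 1] = ids[:, 1:]

    n_pred = full_mask.sum()
    if n_pred == 0:
        raise ValueError("empty loss mask")
    picked = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
    loss = -(np.log(np.maximum(picked, 1e-12)) * full_mask).sum() / n_pred

    dlogits = probs.copy()
    np.put_along_axis(
        dlogits,
        targets[..., None],
        np.take_along_axis(dlogits, targets[..., None], axis=-1) - 1.0,
        axis=-1,
    )
    dlogits *= (full_mask / dt.type(n_pred))[..., None]

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    xf, lnfc = caches["final"]
    grads["W_out"] = xf.reshape(-1, config.embed_dim).T @ dlogits.reshape(-1, config.vocab_size)
    grads["b_out"] = dlogits.sum((0, 1))
    dx, grads["lnf_g"], grads["lnf_b"] = _layernorm_bwd(dlogits @ params["W_out"].T, lnfc)

    H, hd, d = config.n_heads, config.head_dim, config.embed_dim
    cos, sin = caches["rope"]
    for l in reversed(range(config.n_layers)):
        h, ln1c, qr, kr, vh, attn, ctx2, h2, ln2c, gc, a1, m1, m2 = caches[l]
        # MLP branch
        dz2 = dx.copy()
        if m2 is not None:
            dz2 *= m2
        grads[f"l{l}.W2"] = a1.reshape(-1, a1.shape[-1]).T @ dz2.reshape(-1, d)
        grads[f"l{l}.b2"] = dz2.sum((0, 1))
        da1 = dz2 @ params[f"l{l}.W2"].T
        dz1 = _gelu_bwd(da1, gc)
        grads[f"l{l}.W1"] = h2.reshape(-1, d).T @ dz1.reshape(-1, dz1.shape[-1])
        grads[f"l{l}.b1"] = dz1.sum((0, 1))
        dh2 = dz1 @ params[f"l{l}.W1"].T
        dres, grads[f"l{l}.ln2_g"], grads[f"l{l}.ln2_b"] = _layernorm_bwd(dh2, ln2c)
        dx = dx + dres
        # attention branch
        dproj = dx.copy()
        if m1 is not None:
            dproj *= m1
        grads[f"l{l}.Wo"] = ctx2.reshape(-1, d).T @ dproj.reshape(-1, d)
        grads[f"l{l}.bo"] = dproj.sum((0, 1))
        dctx2 = dproj @ params[f"l{l}.Wo"].T
        B_, L_ = dctx2.shape[:2]
        dctx = dctx2.reshape(B_, L_, H, hd).transpose(0, 2, 1, 3)
        dattn = dctx @ vh.transpose(0, 1, 3, 2)
        dvh = attn.transpose(0, 1, 3, 2) @ dctx
        dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
        dscores *= 1.0 / hd**0.5
        dqr = dscores @ kr
        dkr = dscores.transpose(0, 1, 3, 2) @ qr
        dqh = _rot_back(dqr, cos, sin)
        dkh = _rot_back(dkr, cos, sin)
        dq = dqh.transpose(0, 2, 1, 3).reshape(B_, L_, d)
        dk = dkh.transpose(0, 2, 1, 3).reshape(B_, L_, d)
        dv = dvh.transpose(0, 2, 1, 3).reshape(B_, L_, d)
        grads[f"l{l}.Wq"] = h.reshape(-1, d).T @ dq.reshape(-1, d)
        grads[f"l{l}.bq"] = dq.sum((0, 1))
        grads[f"l{l}.Wk"] = h.reshape(-1, d).T @ dk.reshape(-1, d)
        grads[f"l{l}.bk"] = dk.sum((0, 1))
        grads[f"l{l}.Wv"] = h.reshape(-1, d).T @ dv.reshape(-1, d)
        grads[f"l{l}.bv"] = dv.sum((0, 1))
        dh = dq @ params[f"l{l}.Wq"].T + dk @ params[f"l{l}.Wk"].T + dv @ params[f"l{l}.Wv"].T
        dres, grads[f"l{l}.ln1_g"], grads[f"l{l}.ln1_b"] = _layernorm_bwd(dh, ln1c)
        dx = dx + dres

    # embeddings
    C = config.cond_len
    np.add.at(grads["seg_emb"], segment.ravel(), dx.reshape(-1, d))
    tok_part = dx[:, C:, :]
    np.add.at(grads["tok_emb"], ids.ravel(), tok_part.reshape(-1, d))
    if C:
        cond_part = dx[:, :C, :]
        np.add.at(grads["cond_val_emb"], cond_arr.ravel(), cond_part.reshape(-1, d))
        grads["cond_pos_emb"] = cond_part.sum(0)
    return loss, grads


# ---------------------------------------------------------------------------
# training


def _pad_batch(token_ids: list[tuple[int, ...]], pad_id: int):
    """Right-pad with the pad token; one pad per sequence is a real
    end-of-sequence target, the rest are masked out."""
    T = max(len(t) for t in token_ids) + 1
    B = len(token_ids)
    ids = np.full((B, T), pad_id, dtype=np.int64)
    mask = np.zeros((B, T), dtype=np.float64)
    for b, toks in enumerate(token_ids):
        ids[b, : len(toks)] = toks
        mask[b, 1 : len(toks) + 1] = 1.0  # predict tokens 1..n and the final pad
    return ids, mask


def train(
    corpus,
    config: ModelConfig,
    vocabulary,
    n_epochs: int = 100,
    batch_size: int = 32,
    learning_rate: float = 3e-3,
    weight_decay: float = 0.0,
    lr_schedule: str = "cosine",
    verbose: bool = False,
) -> DecoderState:
    """Train the decoder on (smiles, condition) pairs.

    *corpus* is a list of ``(smiles, condition)`` where condition is a
    0/1 fingerprint vector, an 8-long count vector, or None for the
    unconditional model.  Adam, seeded shuffling, per-epoch mean loss kept
    in the returned state's ``loss_history``.  ``lr_schedule`` is either
    "cosine" (decay to 10% of the base rate over training) or "constant".
    """
    if lr_schedule not in ("cosine", "constant"):
        raise ValueError("lr_schedule must be 'cosine' or 'constant'")
    if not corpus:
        raise ValueError("empty training corpus")
    C = config.cond_len
    encoded = []
    for smiles, condition in corpus:
        seq = vocabulary.encode(smiles)
        if C:
            condition = np.asarray(condition, dtype=np.int64)
            if condition.shape != (C,):
                raise ValueError(
                    f"condition length {condition.shape} does not match "
                    f"condition_kind {config.condition_kind}"
                )
        elif condition is not None:
            condition = None
        encoded.append((seq.ids, condition))

    params = init_params(config)
    rng = np.random.default_rng(config.seed + 1)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n_batches_per_epoch = (len(encoded) + batch_size - 1) // batch_size
    total_steps = max(1, n_epochs * n_batches_per_epoch)
    history = []
    idx = np.arange(len(encoded))
    for epoch in range(n_epochs):
        rng.shuffle(idx)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(idx), batch_size):
            batch = [encoded[i] for i in idx[start : start + batch_size]]
            ids, mask = _pad_batch([b[0] for b in batch], vocabulary.pad_id)
            cond = np.stack([b[1] for b in batch]) if C else None
            drng = np.random.default_rng(config.seed + 100_000 + step) if config.dropout else None
            loss, grads = loss_and_grads(params, config, cond, ids, mask, dropout_rng=drng)
            step += 1
            base_lr = learning_rate
            if lr_schedule == "cosine":
                frac = (step - 1) / total_steps
                base_lr = learning_rate * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * frac)))
            lr_t = base_lr * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k in params:
                g = grads[k]
                if weight_decay and k.endswith(("W1", "W2", "Wq", "Wk", "Wv", "Wo", "W_out")):
                    g = g + weight_decay * params[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                params[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
        if verbose and (epoch % 10 == 0 or epoch == n_epochs - 1):
            print(f"epoch {epoch:4d}  loss {history[-1]:.4f}")
    return DecoderState(params, config, vocabulary.content_hash(), history)


# ---------------------------------------------------------------------------
# checkpoint io


def save_state(state: DecoderState, path: str) -> None:
    meta = {
        "config": asdict(state.config),
        "vocab_hash": state.vocab_hash,
        "loss_history": list(map(float, state.loss_history)),
        "param_keys": sorted(state.params),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state.params)


def load_state(path: str, expected_vocab_hash: str | None = None) -> DecoderState:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    if expected_vocab_hash is not None and meta["vocab_hash"] != expected_vocab_hash:
        raise ValueError("checkpoint was trained against a different vocabulary")
    params = {k: data[k] for k in meta["param_keys"]}
    return DecoderState(params, ModelConfig(**meta["config"]), meta["vocab_hash"],
                        meta["loss_history"])
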