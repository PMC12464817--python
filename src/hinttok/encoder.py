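"""A small from-scratch transformer encoder for sequence classification.

The classifier embeds token ids (residues plus the two hint tokens), adds
fixed sinusoidal positional encodings, passes the result through pre-norm
transformer blocks (multi-head self-attention + feed-forward, residual
connections, layer normalization), mean-pools the final hidden states over
non-pad positions, and applies a linear softmax head.  Forward and backward
passes are written directly in numpy; parameters are updated with Adam.

Per-layer hidden states are exposed for sparse-autoencoder analysis: the
state recorded for layer *j* is the residual stream after block *j*,
before the final normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

NEG_INF = -1e9
LN_EPS = 1e-5

#: Scales chosen so token identity and position contribute comparably to
#: the input stream: embeddings are initialized at std EMB_INIT_SCALE and
#: the O(1) sinusoidal encodings are multiplied by POS_SCALE.  With the
#: conventional 0.02-std init a single-token signal is swamped by the
#: positional component and the classifier stalls at the majority class.
EMB_INIT_SCALE = 0.1
POS_SCALE = 0.1


class TrainingDivergedError(RuntimeError):
    """Raised when a non-finite loss is encountered during training."""


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture of the classifier encoder.

    ``vocab_size`` must cover the alphabet, pad and (when hint tokens are
    in use) the two hint ids.  ``checkpoint`` may name an ``.npz`` archive
    of pretrained parameters to start from instead of random init.
    """

    vocab_size: int
    n_classes: int
    n_layers: int = 2
    hidden_dim: int = 64
    n_heads: int = 4
    ffn_dim: Optional[int] = None
    max_len: int = 256
    pooling: str = "mean"
    positional: str = "learned"  # "learned" or "sinusoidal"
    pad_id: int = 0
    checkpoint: Optional[str] = None

    def __post_init__(self) -> None:
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.pooling != "mean":
            raise ValueError("only mean pooling is supported")
        if self.positional not in ("learned", "sinusoidal"):
            raise ValueError("positional must be 'learned' or 'sinusoidal'")
        if self.ffn_dim is None:
            object.__setattr__(self, "ffn_dim", 2 * self.hidden_dim)


def sinusoidal_positions(max_len: int, dim: int, dtype=np.float32) -> np.ndarray:
    pos = np.arange(max_len, dtype=np.float64)[:, None]
    i = np.arange(0, dim, 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, i / dim)
    P = np.zeros((max_len, dim), dtype=np.float64)
    P[:, 0::2] = np.sin(angle)
    P[:, 1::2] = np.cos(angle)[:, : dim // 2]
    return P.astype(dtype)


def _init_params(spec: EncoderSpec, seed: int, dtype) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    D, F, V, C = spec.hidden_dim, spec.ffn_dim, spec.vocab_size, spec.n_classes

    def w(*shape, scale=0.02):
        return (rng.normal(0.0, scale, size=shape)).astype(dtype)

    p: dict[str, np.ndarray] = {"emb": w(V, D, scale=EMB_INIT_SCALE)}
    if spec.positional == "learned":
        p["pos"] = w(spec.max_len, D, scale=EMB_INIT_SCALE)
    for l in range(spec.n_layers):
        pre = f"l{l}."
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[pre + name] = w(D, D)
        for name in ("bq", "bk", "bv", "bo"):
            p[pre + name] = np.zeros(D, dtype=dtype)
        p[pre + "ln1_g"] = np.ones(D, dtype=dtype)
        p[pre + "ln1_b"] = np.zeros(D, dtype=dtype)
        p[pre + "ln2_g"] = np.ones(D, dtype=dtype)
        p[pre + "ln2_b"] = np.zeros(D, dtype=dtype)
        p[pre + "W1"] = w(D, F)
        p[pre + "b1"] = np.zeros(F, dtype=dtype)
        p[pre + "W2"] = w(F, D)
        p[pre + "b2"] = np.zeros(D, dtype=dtype)
    p["lnf_g"] = np.ones(D, dtype=dtype)
    p["lnf_b"] = np.zeros(D, dtype=dtype)
    p["Wc"] = w(D, C)
    p["bc"] = np.zeros(C, dtype=dtype)
    return p


def init_hint_embeddings(
    params: dict[str, np.ndarray],
    hint_ids: tuple[int, int],
    seed: int,
    noise: float = 0.01,
) -> None:
    """Re-initialize hint-token embeddings from the embedding mean + noise.

    Useful when starting from a checkpoint whose vocabulary lacked the
    hint tokens; gives the new tokens a stable, in-distribution start.
    """
    rng = np.random.default_rng(seed)
    emb = params["emb"]
    base = np.delete(emb, list(hint_ids), axis=0).mean(axis=0)
    for hid in hint_ids:
        emb[hid] = base + rng.normal(0.0, noise, size=emb.shape[1]).astype(emb.dtype)


# ---------------------------------------------------------------------------
# Primitive forward/backward pairs
# ---------------------------------------------------------------------------

def _ln_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_bwd(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    return dx, dg, db


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _attn_fwd(x, p, pre, n_heads, key_mask):
    """Multi-head self-attention; `key_mask` (B,T) True at real tokens."""
    B, T, D = x.shape
    dh = D // n_heads

    def heads(z):
        return z.reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)

    q = heads(x @ p[pre + "Wq"] + p[pre + "bq"])
    k = heads(x @ p[pre + "Wk"] + p[pre + "bk"])
    v = heads(x @ p[pre + "Wv"] + p[pre + "bv"])
    s = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh)
    s = s + np.where(key_mask[:, None, None, :], 0.0, NEG_INF).astype(x.dtype)
    A = _softmax(s, axis=-1)
    o = (A @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
    out = o @ p[pre + "Wo"] + p[pre + "bo"]
    return out, (x, q, k, v, A, o)


def _attn_bwd(dout, cache, p, pre, n_heads):
    x, q, k, v, A, o = cache
    B, T, D = x.shape
    dh = D // n_heads
    grads = {}
    grads[pre + "Wo"] = o.reshape(-1, D).T @ dout.reshape(-1, D)
    grads[pre + "bo"] = dout.sum((0, 1))
    do = (dout @ p[pre + "Wo"].T).reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)
    dA = do @ v.transpose(0, 1, 3, 2)
    dv = A.transpose(0, 1, 3, 2) @ do
    ds = A * (dA - (dA * A).sum(-1, keepdims=True))
    ds = ds / np.sqrt(dh)
    dq = ds @ k
    dk = ds.transpose(0, 1, 3, 2) @ q

    def unheads(z):
        return z.transpose(0, 2, 1, 3).reshape(B, T, D)

    dx = np.zeros_like(x)
    for name, dz in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
        flat = unheads(dz)
        grads[pre + name] = x.reshape(-1, D).T @ flat.reshape(-1, D)
        grads[pre + "b" + name[1].lower()] = flat.sum((0, 1))
        dx += flat @ p[pre + name].T
    return dx, grads


def _ffn_fwd(x, p, pre):
    h = x @ p[pre + "W1"] + p[pre + "b1"]
    a = np.maximum(h, 0.0)
    return a @ p[pre + "W2"] + p[pre + "b2"], (x, h, a)


def _ffn_bwd(dout, cache, p, pre):
    x, h, a = cache
    D = x.shape[-1]
    F = a.shape[-1]
    grads = {
        pre + "W2": a.reshape(-1, F).T @ dout.reshape(-1, D),
        pre + "b2": dout.sum((0, 1)),
    }
    da = dout @ p[pre + "W2"].T
    dh = da * (h > 0)
    grads[pre + "W1"] = x.reshape(-1, D).T @ dh.reshape(-1, F)
    grads[pre + "b1"] = dh.sum((0, 1))
    return dh @ p[pre + "W1"].T, grads


def _dropout_mask(rng, shape, p, dtype):
    if rng is None or p <= 0.0:
        return None
    return (rng.random(shape) >= p).astype(dtype) / (1.0 - p)


# ---------------------------------------------------------------------------
# The classifier
# ---------------------------------------------------------------------------

class TinyTransformerClassifier:
    """Seeded numpy transformer classifier with Adam training."""

    def __init__(self, spec: EncoderSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.seed = seed
        self.dtype = dtype
        if spec.checkpoint is not None:
            loaded = np.load(spec.checkpoint)
            self.params = {k: loaded[k].astype(dtype) for k in loaded.files}
        else:
            self.params = _init_params(spec, seed, dtype)
        self.pos = (
            None
            if spec.positional == "learned"
            else POS_SCALE * sinusoidal_positions(spec.max_len, spec.hidden_dim, dtype)
        )
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0

    # -- forward ------------------------------------------------------------

    def _forward(self, ids, train=False, dropout=0.0, rng=None, collect_hidden=False):
        p, spec = self.params, self.spec
        B, T = ids.shape
        if T > spec.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {spec.max_len}")
        mask = ids != spec.pad_id  # (B, T)
        pos = p["pos"] if spec.positional == "learned" else self.pos
        h = p["emb"][ids] + pos[:T]
        caches = []
        hidden = []
        for l in range(spec.n_layers):
            pre = f"l{l}."
            u, c_ln1 = _ln_fwd(h, p[pre + "ln1_g"], p[pre + "ln1_b"])
            a, c_att = _attn_fwd(u, p, pre, spec.n_heads, mask)
            m1 = _dropout_mask(rng if train else None, a.shape, dropout, self.dtype)
            if m1 is not None:
                a = a * m1
            h = h + a
            v, c_ln2 = _ln_fwd(h, p[pre + "ln2_g"], p[pre + "ln2_b"])
            f, c_ffn = _ffn_fwd(v, p, pre)
            m2 = _dropout_mask(rng if train else None, f.shape, dropout, self.dtype)
            if m2 is not None:
                f = f * m2
            h = h + f
            caches.append((c_ln1, c_att, m1, c_ln2, c_ffn, m2))
            if collect_hidden:
                hidden.append(h.copy())
        hf, c_lnf = _ln_fwd(h, p["lnf_g"], p["lnf_b"])
        fmask = mask.astype(self.dtype)[:, :, None]
        counts = np.maximum(fmask.sum(1), 1.0)
        pooled = (hf * fmask).sum(1) / counts
        logits = pooled @ p["Wc"] + p["bc"]
        cache = (ids, mask, caches, c_lnf, fmask, counts, pooled)
        return logits, cache, hidden

    def logits(self, ids: np.ndarray) -> np.ndarray:
        out, _, _ = self._forward(np.asarray(ids))
        return out

    def predict(self, ids: np.ndarray, batch_size: int = 64) -> np.ndarray:
        ids = np.asarray(ids)
        preds = [
            self.logits(ids[i : i + batch_size]).argmax(-1)
            for i in range(0, len(ids), batch_size)
        ]
        return np.concatenate(preds) if preds else np.zeros(0, dtype=int)

    def hidden_states(self, ids: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Residual-stream states per layer: shape (n_layers, N, T, D)."""
        ids = np.asarray(ids)
        chunks = []
        for i in range(0, len(ids), batch_size):
            _, _, hid = self._forward(ids[i : i + batch_size], collect_hidden=True)
            chunks.append(np.stack(hid))
        return np.concatenate(chunks, axis=1)

    # -- backward -----------------------------------------------------------

    def loss_and_grads(self, ids, y, dropout=0.0, rng=None):
        p, spec = self.params, self.spec
        logits, cache, _ = self._forward(
            np.asarray(ids), train=True, dropout=dropout, rng=rng
        )
        ids_a, mask, caches, c_lnf, fmask, counts, pooled = cache
        B = len(ids_a)
        probs = _softmax(logits.astype(np.float64), -1)
        loss = -np.mean(np.log(probs[np.arange(B), y] + 1e-12))
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"non-finite loss {loss!r}; logits range "
                f"[{np.min(logits)}, {np.max(logits)}]"
            )
        dlogits = probs.astype(self.dtype)
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        grads: dict[str, np.ndarray] = {
            "Wc": pooled.T @ dlogits,
            "bc": dlogits.sum(0),
        }
        dpooled = dlogits @ p["Wc"].T
        dhf = (dpooled[:, None, :] / counts[:, None, :]) * fmask
        dh, grads["lnf_g"], grads["lnf_b"] = _ln_bwd(dhf, c_lnf)

        for l in reversed(range(spec.n_layers)):
            pre = f"l{l}."
            c_ln1, c_att, m1, c_ln2, c_ffn, m2 = caches[l]
            df = dh if m2 is None else dh * m2
            dv, g_ffn = _ffn_bwd(df, c_ffn, p, pre)
            grads.update(g_ffn)
            dh2, grads[pre + "ln2_g"], grads[pre + "ln2_b"] = _ln_bwd(dv, c_ln2)
            dh = dh + dh2
            da = dh if m1 is None else dh * m1
            du, g_att = _attn_bwd(da, c_att, p, pre, spec.n_heads)
            grads.update(g_att)
            dh1, grads[pre + "ln1_g"], grads[pre + "ln1_b"] = _ln_bwd(du, c_ln1)
            dh = dh + dh1

        demb = np.zeros_like(p["emb"])
        np.add.at(demb, ids_a, dh)
        grads["emb"] = demb
        if spec.positional == "learned":
            dpos = np.zeros_like(p["pos"])
            dpos[: dh.shape[1]] = dh.sum(0)
            grads["pos"] = dpos
        return float(loss), grads

    # -- optimization -------------------------------------------------------

    def adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m.setdefault(k, np.zeros_like(self.params[k]))
            v = self._adam_v.setdefault(k, np.zeros_like(self.params[k]))
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(self.dtype)

    def train_epoch(self, ids, y, rng, lr=1e-3, batch_size=32, dropout=0.0) -> float:
        """One seeded pass over the data; returns the mean minibatch loss."""
        ids, y = np.asarray(ids), np.asarray(y)
        order = rng.permutation(len(ids))
        losses = []
        for i in range(0, len(ids), batch_size):
            sl = order[i : i + batch_size]
            loss, grads = self.loss_and_grads(ids[sl], y[sl], dropout, rng)
            self.adam_step(grads, lr)
            losses.append(loss)
        return float(np.mean(losses)) if losses else 0.0

    # -- state --------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in state.items()}
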