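"""Minimal NumPy transformer encoder with hand-written backpropagation.

This is the computational core of the desk-scale reference masked language
model: token embeddings plus fixed sinusoidal positional encodings feed a
stack of pre-LayerNorm blocks (multi-head self-attention, then a two-layer
ReLU feed-forward, both residual), finished by a final LayerNorm.  Because
positional encodings are analytic rather than learned, input length is not
baked into the weights.

All math is float64 and every backward pass is verified against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_NEG_INF = -1e30
_LN_EPS = 1e-5


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Standard sin/cos positional encoding, shape (length, dim)."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim // 2)[None, :]
    angles = pos / (10000.0 ** (2 * i / dim))
    enc = np.zeros((length, dim))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles[:, : dim - dim // 2])
    return enc


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over rows; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), targets], 1e-300, None)).mean())
    dlogits = p
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


def binary_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Sigmoid BCE over a 1-D logit vector; returns (loss, dlogits)."""
    p = 1.0 / (1.0 + np.exp(-logits))
    loss = float(
        -(targets * np.log(np.clip(p, 1e-300, None))
          + (1 - targets) * np.log(np.clip(1 - p, 1e-300, None))).mean()
    )
    return loss, (p - targets) / logits.shape[0]


def _layernorm_forward(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


class AdamOptimizer:
    """Adam over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class EncoderConfig:
    vocab_size: int
    dim: int = 64
    n_layers: int = 2
    n_heads: int = 2
    ff_dim: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.dim % self.n_heads != 0:
            raise ValueError(f"dim={self.dim} not divisible by n_heads={self.n_heads}")
        if self.dim % 2 != 0:
            raise ValueError("dim must be even for sinusoidal encodings")


class TransformerEncoder:
    """Forward/backward transformer encoder over integer token ids.

    Padding positions (``mask == False``) are excluded from attention keys,
    so they never influence real positions; their own outputs carry no loss.
    """

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, f, V = config.dim, config.ff_dim, config.vocab_size
        std = 0.02
        p: dict[str, np.ndarray] = {"tok_emb": rng.normal(0, std, (V, d))}
        for l in range(config.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"l{l}.{name}"] = rng.normal(0, std, (d, d))
            p[f"l{l}.ln1.g"] = np.ones(d)
            p[f"l{l}.ln1.b"] = np.zeros(d)
            p[f"l{l}.ln2.g"] = np.ones(d)
            p[f"l{l}.ln2.b"] = np.zeros(d)
            p[f"l{l}.W1"] = rng.normal(0, std, (d, f))
            p[f"l{l}.b1"] = np.zeros(f)
            p[f"l{l}.W2"] = rng.normal(0, std, (f, d))
            p[f"l{l}.b2"] = np.zeros(d)
        p["lnf.g"] = np.ones(d)
        p["lnf.b"] = np.zeros(d)
        self.params = p

    # ------------------------------------------------------------------
    def forward(self, ids: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, dict]:
        """ids (B, L) int; mask (B, L) bool, True = real token.

        Returns final hidden states (B, L, d) and a cache for backward.
        """
        cfg = self.config
        p = self.params
        B, L = ids.shape
        d, h = cfg.dim, cfg.n_heads
        dh = d // h
        x = p["tok_emb"][ids] + sinusoidal_positions(L, d)[None]
        key_bias = np.where(mask, 0.0, _NEG_INF)[:, None, None, :]  # (B,1,1,L)
        cache: dict = {"ids": ids, "mask": mask, "layers": []}
        for l in range(cfg.n_layers):
            lc: dict = {"x_in": x}
            n1, ln1c = _layernorm_forward(x, p[f"l{l}.ln1.g"], p[f"l{l}.ln1.b"])
            Q = n1 @ p[f"l{l}.Wq"]
            K = n1 @ p[f"l{l}.Wk"]
            V = n1 @ p[f"l{l}.Wv"]
            Qh = Q.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            Kh = K.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            Vh = V.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            S = Qh @ Kh.transpose(0, 1, 3, 2) / np.sqrt(dh) + key_bias
            A = softmax(S)
            Ch = A @ Vh
            C = Ch.transpose(0, 2, 1, 3).reshape(B, L, d)
            O = C @ p[f"l{l}.Wo"]
            x2 = x + O
            n2, ln2c = _layernorm_forward(x2, p[f"l{l}.ln2.g"], p[f"l{l}.ln2.b"])
            pre = n2 @ p[f"l{l}.W1"] + p[f"l{l}.b1"]
            F1 = np.maximum(pre, 0.0)
            F2 = F1 @ p[f"l{l}.W2"] + p[f"l{l}.b2"]
            x = x2 + F2
            lc.update(n1=n1, ln1c=ln1c, Qh=Qh, Kh=Kh, Vh=Vh, A=A, C=C,
                      x2=x2, n2=n2, ln2c=ln2c, pre=pre, F1=F1)
            cache["layers"].append(lc)
        hfinal, lnfc = _layernorm_forward(x, p["lnf.g"], p["lnf.b"])
        cache["lnfc"] = lnfc
        return hfinal, cache

    # ------------------------------------------------------------------
    def backward(self, dh_final: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradient of a scalar loss w.r.t. all parameters, given the
        gradient at the final hidden states."""
        cfg = self.config
        p = self.params
        ids = cache["ids"]
        B, L = ids.shape
        d, h = cfg.dim, cfg.n_heads
        dh_ = d // h
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        dx, dg, db = _layernorm_backward(dh_final, cache["lnfc"])
        grads["lnf.g"] += dg
        grads["lnf.b"] += db

        for l in reversed(range(cfg.n_layers)):
            lc = cache["layers"][l]
            # feed-forward
            dF2 = dx
            grads[f"l{l}.W2"] += lc["F1"].reshape(-1, cfg.ff_dim).T @ dF2.reshape(-1, d)
            grads[f"l{l}.b2"] += dF2.sum(axis=(0, 1))
            dF1 = dF2 @ p[f"l{l}.W2"].T
            dpre = dF1 * (lc["pre"] > 0)
            grads[f"l{l}.W1"] += lc["n2"].reshape(-1, d).T @ dpre.reshape(-1, cfg.ff_dim)
            grads[f"l{l}.b1"] += dpre.sum(axis=(0, 1))
            dn2 = dpre @ p[f"l{l}.W1"].T
            dx2_ln, dg, db = _layernorm_backward(dn2, lc["ln2c"])
            grads[f"l{l}.ln2.g"] += dg
            grads[f"l{l}.ln2.b"] += db
            dx2 = dx + dx2_ln
            # attention
            dO = dx2
            grads[f"l{l}.Wo"] += lc["C"].reshape(-1, d).T @ dO.reshape(-1, d)
            dC = dO @ p[f"l{l}.Wo"].T
            dCh = dC.reshape(B, L, h, dh_).transpose(0, 2, 1, 3)
            dA = dCh @ lc["Vh"].transpose(0, 1, 3, 2)
            dVh = lc["A"].transpose(0, 1, 3, 2) @ dCh
            A = lc["A"]
            dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
            dS /= np.sqrt(dh_)
            dQh = dS @ lc["Kh"]
            dKh = dS.transpose(0, 1, 3, 2) @ lc["Qh"]
            dQ = dQh.transpose(0, 2, 1, 3).reshape(B, L, d)
            dK = dKh.transpose(0, 2, 1, 3).reshape(B, L, d)
            dV = dVh.transpose(0, 2, 1, 3).reshape(B, L, d)
            n1f = lc["n1"].reshape(-1, d)
            grads[f"l{l}.Wq"] += n1f.T @ dQ.reshape(-1, d)
            grads[f"l{l}.Wk"] += n1f.T @ dK.reshape(-1, d)
            grads[f"l{l}.Wv"] += n1f.T @ dV.reshape(-1, d)
            dn1 = dQ @ p[f"l{l}.Wq"].T + dK @ p[f"l{l}.Wk"].T + dV @ p[f"l{l}.Wv"].T
            dx_ln, dg, db = _layernorm_backward(dn1, lc["ln1c"])
            grads[f"l{l}.ln1.g"] += dg
            grads[f"l{l}.ln1.b"] += db
            dx = dx2 + dx_ln

        np.add.at(grads["tok_emb"], ids, dx)
        return grads


def pad_batch(id_seqs: list[tuple[int, ...]], pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad variable-length id sequences; returns (ids, mask)."""
    B = len(id_seqs)
    L = max(len(s) for s in id_seqs)
    ids = np.full((B, L), pad_id, dtype=np.int64)
    mask = np.zeros((B, L), dtype=bool)
    for i, s in enumerate(id_seqs):
        ids[i, : len(s)] = s
        mask[i, : len(s)] = True
    return ids, mask


def mean_pool(hidden: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean over real positions; returns (pooled (B, d), counts (B,))."""
    counts = mask.sum(axis=1)
    pooled = (hidden * mask[:, :, None]).sum(axis=1) / counts[:, None]
    return pooled, counts


def mean_pool_backward(dpooled: np.ndarray, mask: np.ndarray) -> np.ndarray:
    counts = mask.sum(axis=1)
    return (dpooled[:, None, :] / counts[:, None, None]) * mask[:, :, None]
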