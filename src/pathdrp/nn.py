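"""Minimal NumPy neural-network core for the subpathway classifier.

Implements exactly the layer stack the classifier needs — a height-1 1D
convolution over the omics channels, same-length max pooling, dropout,
optional additive attention over the subpathway positions, and three dense
layers ending in softmax — with hand-derived gradients and an Adam
optimizer.  Everything is deterministic given a :class:`numpy.random.Generator`.

Shapes use B = batch, K = number of subpathway positions, C = omics
channels (3), F = conv filters (100).
"""

from __future__ import annotations

import math

import numpy as np


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def maxpool_forward(h: np.ndarray, size: int, stride: int):
    """Max pooling along axis 1. stride=1 keeps the length (same padding);
    stride=size is the non-overlapping reading. Returns (out, argmax_abs)."""
    b, k, f = h.shape
    if stride == 1:
        pad = (size - 1) // 2
        neg = np.full((b, pad, f), -np.inf)
        padded = np.concatenate([neg, h, neg], axis=1)
        out_len, offset = k, -pad
    else:
        out_len = math.ceil(k / stride)
        need = (out_len - 1) * stride + size
        neg = np.full((b, need - k, f), -np.inf)
        padded = np.concatenate([h, neg], axis=1)
        offset = 0
    out = np.empty((b, out_len, f))
    idx = np.empty((b, out_len, f), dtype=np.int64)
    for i in range(out_len):
        win = padded[:, i * stride : i * stride + size, :]
        a = win.argmax(axis=1)
        out[:, i, :] = np.take_along_axis(win, a[:, None, :], axis=1)[:, 0, :]
        idx[:, i, :] = a + i * stride + offset
    return out, idx


def maxpool_backward(grad: np.ndarray, idx: np.ndarray, k: int) -> np.ndarray:
    b, out_len, f = grad.shape
    dh = np.zeros((b, k, f))
    bi = np.broadcast_to(np.arange(b)[:, None, None], grad.shape)
    fi = np.broadcast_to(np.arange(f)[None, None, :], grad.shape)
    np.add.at(dh, (bi, idx, fi), grad)
    return dh


class ConvAttentionNet:
    """1D CNN (optionally with additive attention) for (K x C) inputs.

    Layer stack: reshape(CK -> K x C) -> conv(F filters, kernel height 1 over
    all C channels, ReLU) -> maxpool(size 3) -> dropout(0.5) ->
    [attention over the K positions] -> flatten -> dense(512, ReLU) ->
    dense(256, ReLU) -> dense(2, softmax).

    The attention scores each position i by e_i = v^T tanh(W c + U y_i)
    against a learnable context vector c, normalizes a = softmax(e), and
    rescales the sequence by K*a_i so uniform attention is the identity map
    (the attention-free network is recovered exactly).
    """

    def __init__(
        self,
        K: int,
        with_attention: bool,
        n_channels: int = 3,
        n_filters: int = 100,
        pool_size: int = 3,
        pool_stride: int = 1,
        dropout: float = 0.5,
        dense1: int = 512,
        dense2: int = 256,
        n_classes: int = 2,
        attn_dim: int = 32,
        seed: int = 0,
    ) -> None:
        if K < 1:
            raise ValueError("K must be >= 1")
        self.K, self.C, self.F = K, n_channels, n_filters
        self.with_attention = with_attention
        self.pool_size, self.pool_stride = pool_size, pool_stride
        self.pooled_len = K if pool_stride == 1 else math.ceil(K / pool_stride)
        self.dropout = dropout
        self.dims = (dense1, dense2, n_classes)
        self.attn_dim = attn_dim
        rng = np.random.default_rng(seed)
        flat = self.pooled_len * n_filters
        p: dict[str, np.ndarray] = {
            "Wc": glorot(rng, (n_channels, n_filters)),
            "bc": np.zeros(n_filters),
            "W1": glorot(rng, (flat, dense1)),
            "b1": np.zeros(dense1),
            "W2": glorot(rng, (dense1, dense2)),
            "b2": np.zeros(dense2),
            "W3": glorot(rng, (dense2, n_classes)),
            "b3": np.zeros(n_classes),
        }
        if with_attention:
            p["Wa"] = glorot(rng, (attn_dim, n_filters))
            p["Ua"] = glorot(rng, (attn_dim, n_filters))
            p["va"] = rng.standard_normal(attn_dim) * 0.1
            p["c"] = rng.standard_normal(n_filters) * 0.1
        self.params = p

    # -- forward -----------------------------------------------------------

    def forward(
        self, x: np.ndarray, train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """x: (B, C*K) flat vectors. Returns (probs, cache)."""
        p = self.params
        b = x.shape[0]
        xr = x.reshape(b, self.K, self.C)
        z_conv = xr @ p["Wc"] + p["bc"]
        h1 = np.maximum(z_conv, 0.0)
        pooled, pool_idx = maxpool_forward(h1, self.pool_size, self.pool_stride)
        if train and self.dropout > 0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            keep = 1.0 - self.dropout
            mask = (rng.random(pooled.shape) < keep) / keep
            dropped = pooled * mask
        else:
            mask = None
            dropped = pooled
        cache: dict = {
            "xr": xr, "z_conv": z_conv, "pool_idx": pool_idx,
            "mask": mask, "dropped": dropped,
        }
        seq = dropped
        alphas = None
        if self.with_attention:
            seq, attn_cache = self._attention_forward(dropped)
            alphas = attn_cache["alpha"]
            cache["attn"] = attn_cache
        flat = seq.reshape(b, -1)
        z1 = flat @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        z3 = a2 @ p["W3"] + p["b3"]
        probs = softmax(z3)
        cache.update(flat=flat, z1=z1, a1=a1, z2=z2, a2=a2, probs=probs,
                     alphas=alphas)
        return probs, cache

    def _attention_forward(self, y: np.ndarray):
        p = self.params
        a_ctx = p["Wa"] @ p["c"]                       # (da,)
        t = np.tanh(a_ctx[None, None, :] + y @ p["Ua"].T)   # (B,K,da)
        e = t @ p["va"]                                # (B,K)
        alpha = softmax(e, axis=1)
        out = self.pooled_len * alpha[:, :, None] * y
        return out, {"y": y, "t": t, "e": e, "alpha": alpha}

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(x, train=False)
        return probs

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        if not self.with_attention:
            raise ValueError("model was built without attention")
        _, cache = self.forward(x, train=False)
        return cache["alphas"]

    # -- backward ----------------------------------------------------------

    def loss_and_grads(
        self, x: np.ndarray, y_onehot: np.ndarray,
        rng: np.random.Generator | None = None, train: bool = True,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean categorical cross-entropy and parameter gradients."""
        p = self.params
        b = x.shape[0]
        probs, c = self.forward(x, train=train, rng=rng)
        eps = 1e-12
        loss = float(-(y_onehot * np.log(probs + eps)).sum() / b)

        g: dict[str, np.ndarray] = {}
        dz3 = (probs - y_onehot) / b
        g["W3"] = c["a2"].T @ dz3
        g["b3"] = dz3.sum(0)
        da2 = dz3 @ p["W3"].T
        dz2 = da2 * (c["z2"] > 0)
        g["W2"] = c["a1"].T @ dz2
        g["b2"] = dz2.sum(0)
        da1 = dz2 @ p["W2"].T
        dz1 = da1 * (c["z1"] > 0)
        g["W1"] = c["flat"].T @ dz1
        g["b1"] = dz1.sum(0)
        dflat = dz1 @ p["W1"].T
        dseq = dflat.reshape(b, self.pooled_len, self.F)
        if self.with_attention:
            dseq = self._attention_backward(dseq, c["attn"], g)
        if c["mask"] is not None:
            dseq = dseq * c["mask"]
        dpool = maxpool_backward(dseq, c["pool_idx"], self.K)
        dzc = dpool * (c["z_conv"] > 0)
        g["Wc"] = np.einsum("bkc,bkf->cf", c["xr"], dzc)
        g["bc"] = dzc.sum((0, 1))
        return loss, g

    def _attention_backward(self, grad, ac, g):
        p = self.params
        y, t, alpha = ac["y"], ac["t"], ac["alpha"]
        kk = self.pooled_len
        dalpha = kk * (grad * y).sum(-1)                       # (B,K)
        dy = kk * alpha[:, :, None] * grad                      # direct term
        de = alpha * (dalpha - (alpha * dalpha).sum(1, keepdims=True))
        dt = de[:, :, None] * p["va"][None, None, :]
        u = dt * (1.0 - t * t)                                  # (B,K,da)
        g["va"] = np.einsum("bk,bkd->d", de, t)
        g["Ua"] = np.einsum("bkd,bkf->df", u, y)
        da_ctx = u.sum((0, 1))
        g["Wa"] = np.outer(da_ctx, p["c"])
        g["c"] = p["Wa"].T @ da_ctx
        dy = dy + u @ p["Ua"]
        return dy

    # -- introspection -----------------------------------------------------

    def architecture_summary(self) -> list[dict]:
        """Layer-by-layer output shapes and parameter counts (JSON-able)."""
        d1, d2, nc = self.dims
        flat = self.pooled_len * self.F
        rows = [
            {"layer": "input", "output_shape": [self.C * self.K], "n_params": 0},
            {"layer": "reshape", "output_shape": [self.K, self.C], "n_params": 0},
            {"layer": "conv1d", "output_shape": [self.K, self.F],
             "n_params": self.C * self.F + self.F},
            {"layer": "maxpool", "output_shape": [self.pooled_len, self.F],
             "n_params": 0},
            {"layer": "dropout", "output_shape": [self.pooled_len, self.F],
             "n_params": 0},
        ]
        if self.with_attention:
            rows.append({
                "layer": "attention",
                "output_shape": [self.pooled_len, self.F],
                "n_params": 2 * self.attn_dim * self.F + self.attn_dim + self.F,
            })
        rows += [
            {"layer": "flatten", "output_shape": [flat], "n_params": 0},
            {"layer": "dense1", "output_shape": [d1], "n_params": flat * d1 + d1},
            {"layer": "dense2", "output_shape": [d2], "n_params": d1 * d2 + d2},
            {"layer": "softmax", "output_shape": [nc], "n_params": d2 * nc + nc},
        ]
        return rows

    def weights_checksum(self) -> float:
        return float(sum(np.abs(v).sum() for v in self.params.values()))

    def save(self, path) -> None:
        np.savez(path, **self.params)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for k in self.params:
                self.params[k] = data[k]


class Adam:
    """Standard Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
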