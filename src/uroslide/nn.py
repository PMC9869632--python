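"""A compact convolutional network in plain numpy.

Two 3x3 conv layers with ReLU and 2x2 max-pooling, then two fully connected
layers onto six logits. Stride-1 convolutions use an im2col formulation so
forward and backward passes are matrix products. Everything is float32 and
deterministic for a fixed seed; there is no framework dependency, so a
serialized model is just its weight arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallCNN", "SGDMomentum", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _conv_forward(x, W, b):
    # x (N,C,H,W), W (F,C,3,3), pad 1, stride 1
    N, C, H, Wd = x.shape
    F = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))          # N,C,H,W,3,3
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * H * Wd, C * 9)
    out = cols @ W.reshape(F, -1).T + b
    out = out.reshape(N, H, Wd, F).transpose(0, 3, 1, 2)
    return out, (cols, x.shape, W)


def _conv_backward(dout, cache):
    cols, xshape, W = cache
    N, C, H, Wd = xshape
    F = W.shape[0]
    d2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, F)
    dW = (d2.T @ cols).reshape(W.shape)
    db = d2.sum(axis=0)
    dcols = (d2 @ W.reshape(F, -1)).reshape(N, H, Wd, C, 3, 3)
    dxp = np.zeros((N, C, H + 2, Wd + 2), dtype=dout.dtype)
    dcols = dcols.transpose(0, 3, 1, 2, 4, 5)                   # N,C,H,W,3,3
    for i in range(3):
        for j in range(3):
            dxp[:, :, i:i + H, j:j + Wd] += dcols[..., i, j]
    return dxp[:, :, 1:H + 1, 1:Wd + 1], dW, db


def _pool_forward(x):
    N, C, H, W = x.shape
    xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(N, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool_backward(dout, cache):
    idx, xshape = cache
    N, C, H, W = xshape
    dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx).reshape(N, C, H, W)


class SmallCNN:
    """conv(3->c1)-relu-pool-conv(c1->c2)-relu-pool-fc(hidden)-relu-fc(6)."""

    def __init__(self, input_size: int = 32, channels: tuple[int, int] = (8, 16),
                 hidden: int = 64, n_classes: int = 6, seed: int = 0):
        if input_size % 4 != 0:
            raise ValueError("input_size must be divisible by 4 (two 2x2 pools)")
        self.input_size = input_size
        self.channels = channels
        self.hidden = hidden
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        c1, c2 = channels
        flat = c2 * (input_size // 4) ** 2

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
                    ).astype(np.float32)

        self.params: dict[str, np.ndarray] = {
            "W1": he((c1, 3, 3, 3), 3 * 9), "b1": np.zeros(c1, np.float32),
            "W2": he((c2, c1, 3, 3), c1 * 9), "b2": np.zeros(c2, np.float32),
            "W3": he((flat, hidden), flat), "b3": np.zeros(hidden, np.float32),
            "W4": he((hidden, n_classes), hidden),
            "b4": np.zeros(n_classes, np.float32),
        }

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits for a batch x of shape (N, 3, S, S), float32."""
        p = self.params
        a1, c1 = _conv_forward(x, p["W1"], p["b1"])
        r1 = np.maximum(a1, 0)
        p1, cp1 = _pool_forward(r1)
        a2, c2 = _conv_forward(p1, p["W2"], p["b2"])
        r2 = np.maximum(a2, 0)
        p2, cp2 = _pool_forward(r2)
        flat = p2.reshape(p2.shape[0], -1)
        h = flat @ p["W3"] + p["b3"]
        rh = np.maximum(h, 0)
        logits = rh @ p["W4"] + p["b4"]
        if not want_cache:
            return logits
        return logits, (c1, a1, cp1, c2, a2, cp2, p2.shape, flat, h, rh)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and parameter gradients for integer labels y."""
        p = self.params
        logits, cache = self.forward(x, want_cache=True)
        c1, a1, cp1, c2, a2, cp2, p2shape, flat, h, rh = cache
        n = x.shape[0]
        probs = softmax(logits)
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads: dict[str, np.ndarray] = {}
        grads["W4"] = rh.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        drh = dlogits @ p["W4"].T
        dh = drh * (h > 0)
        grads["W3"] = flat.T @ dh
        grads["b3"] = dh.sum(axis=0)
        dflat = dh @ p["W3"].T
        dp2 = dflat.reshape(p2shape).astype(np.float32)
        dr2 = _pool_backward(dp2, cp2)
        da2 = dr2 * (a2 > 0)
        dp1, grads["W2"], grads["b2"] = _conv_backward(da2, c2)
        dr1 = _pool_backward(dp1, cp1)
        da1 = dr1 * (a1 > 0)
        _, grads["W1"], grads["b1"] = _conv_backward(da1, c1)
        return loss, logits, grads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))


class SGDMomentum:
    """SGD with classical momentum and decoupled-style L2 weight decay:
    v <- mu*v - lr*(g + wd*w); w <- w + v."""

    def __init__(self, params: dict[str, np.ndarray], momentum: float,
                 weight_decay: float):
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> None:
        for k, w in params.items():
            g = grads[k] + self.weight_decay * w
            v = self.velocity[k]
            v *= self.momentum
            v -= lr * g.astype(np.float32)
            w += v
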