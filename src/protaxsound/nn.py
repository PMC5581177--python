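"""A minimal dense/convolutional network in NumPy.

Desk-scale by construction: two 3x3 convolution blocks with 2x2 max pooling,
global average pooling and a softmax head — a few thousand parameters.
Training is plain minibatch Adam on the cross-entropy.  Written directly in
NumPy (im2col convolutions) so the classifier has no heavyweight framework
dependency; float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallConvNet"]


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution.  x: (B,C,H,W); w: (F,C,3,3)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B,C,H,W,3,3)
    out = np.tensordot(cols, w, axes=([1, 4, 5], [1, 2, 3]))  # (B,H,W,F)
    out = np.transpose(out, (0, 3, 1, 2)) + b[None, :, None, None]
    return out.astype(np.float32), cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, w: np.ndarray):
    dw = np.tensordot(dout, cols, axes=([0, 2, 3], [0, 2, 3]))  # (F,C,3,3)
    db = dout.sum(axis=(0, 2, 3))
    dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dcols = sliding_window_view(dp, (3, 3), axis=(2, 3))  # (B,F,H,W,3,3)
    w_rot = w[:, :, ::-1, ::-1]
    dx = np.tensordot(dcols, w_rot, axes=([1, 4, 5], [0, 2, 3]))  # (B,H,W,C)
    return np.transpose(dx, (0, 3, 1, 2)).astype(np.float32), dw.astype(np.float32), db.astype(np.float32)


def _pool2(x: np.ndarray):
    """2x2 max pooling (stride 2), trailing odd row/col cropped."""
    b, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, :, : h2 * 2, : w2 * 2].reshape(b, c, h2, 2, w2, 2)
    out = xc.max(axis=(3, 5))
    mask = xc == out[:, :, :, None, :, None]
    return out, (mask, (h, w))


def _pool2_backward(dout: np.ndarray, cache):
    mask, (h, w) = cache
    b, c, h2, w2 = dout.shape
    dx = (mask * dout[:, :, :, None, :, None]).reshape(b, c, h2 * 2, w2 * 2)
    out = np.zeros((b, c, h, w), dtype=np.float32)
    out[:, :, : h2 * 2, : w2 * 2] = dx
    return out


class SmallConvNet:
    """conv(3x3,F1)-relu-pool - conv(3x3,F2)-relu-pool - time-mean - dense-softmax.

    The readout averages over time only and keeps the (channel, frequency-row)
    grid, because absolute frequency position carries the class information in
    a spectrogram while the time position of a vocalization does not.
    ``input_shape`` (n_mels, n_frames) fixes the dense-layer fan-in.
    """

    def __init__(self, n_classes: int, input_shape: tuple[int, int],
                 filters=(8, 16), rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        f1, f2 = filters
        h2 = (input_shape[0] // 2) // 2  # frequency rows after two 2x2 pools
        self._h2 = h2
        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.params = {
            "w1": he((f1, 1, 3, 3), 9),
            "b1": np.zeros(f1, dtype=np.float32),
            "w2": he((f2, f1, 3, 3), 9 * f1),
            "b2": np.zeros(f2, dtype=np.float32),
            "wd": he((f2 * h2, n_classes), f2 * h2),
            "bd": np.zeros(n_classes, dtype=np.float32),
        }
        self._adam = {k: [np.zeros_like(v), np.zeros_like(v)] for k, v in self.params.items()}
        self._t = 0

    def forward(self, x: np.ndarray, cache: bool = False):
        p = self.params
        z1, c1 = _conv_forward(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0)
        p1, pc1 = _pool2(a1)
        z2, c2 = _conv_forward(p1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0)
        p2, pc2 = _pool2(a2)
        b = x.shape[0]
        g = p2.mean(axis=3).reshape(b, -1)  # time-mean, keep (F2, H2)
        logits = g @ p["wd"] + p["bd"]
        if not cache:
            return logits
        return logits, (x, z1, c1, pc1, p1, z2, c2, pc2, p2, g)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and parameter gradients.  y: int labels."""
        logits, cache = self.forward(x, cache=True)
        _, z1, c1, pc1, p1, z2, c2, pc2, p2, g = cache
        b = x.shape[0]
        logits = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(probs[np.arange(b), y] + 1e-12))
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        dlogits /= b
        grads = {}
        grads["wd"] = g.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dg = (dlogits @ self.params["wd"].T).reshape(p2.shape[:3])  # (B,F2,H2)
        w = p2.shape[3]
        dp2 = np.broadcast_to((dg / w)[:, :, :, None], p2.shape).astype(np.float32)
        da2 = _pool2_backward(dp2, pc2)
        dz2 = da2 * (z2 > 0)
        dp1, grads["w2"], grads["b2"] = _conv_backward(dz2, c2, self.params["w2"])
        da1 = _pool2_backward(dp1, pc1)
        dz1 = da1 * (z1 > 0)
        _, grads["w1"], grads["b1"] = _conv_backward(dz1, c1, self.params["w1"])
        return float(loss), grads

    def adam_step(self, grads, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        for k, g in grads.items():
            m, v = self._adam[k]
            m[:] = beta1 * m + (1 - beta1) * g
            v[:] = beta2 * v + (1 - beta2) * g * g
            mhat = m / (1 - beta1**self._t)
            vhat = v / (1 - beta2**self._t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        outs = []
        for i in range(0, x.shape[0], batch):
            logits = self.forward(x[i : i + batch])
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            outs.append(e / e.sum(axis=1, keepdims=True))
        return np.vstack(outs)
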