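"""A small numpy encoder-decoder for per-pixel structure labeling.

SegNet-style topology: two conv+max-pool encoder stages, a bottleneck conv,
and a decoder that upsamples with the stored max-pooling indices and mirrors
the encoder widths, ending in a 10-way per-pixel classifier.  3x3
same-padding convolutions are computed as nine shifted matrix products
(cheaper on CPU than materializing an im2col patch matrix); optimization is
Adam with classic L2 weight decay added to the gradient.

Spatial sizes must be divisible by 4 (two 2x2 pooling stages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class Conv3x3:
    """3x3 same-padding convolution with bias; He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xpad = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(np.float32, copy=False)
        n, c, h, w = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xpad = xpad
        out = np.zeros((n, h, w, self.w.shape[0]), dtype=np.float32)
        for di in range(3):
            for dj in range(3):
                out += np.tensordot(
                    xpad[:, :, di : di + h, dj : dj + w], self.w[:, :, di, dj], axes=([1], [1])
                )
        out += self.b
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.astype(np.float32, copy=False)
        n, co, h, w = dy.shape
        xpad = self._xpad
        dxpad = np.zeros_like(xpad)
        # gradients written in place: the optimizer holds references to dw/db
        for di in range(3):
            for dj in range(3):
                xs = xpad[:, :, di : di + h, dj : dj + w]
                self.dw[:, :, di, dj] = np.tensordot(dy, xs, axes=([0, 2, 3], [0, 2, 3]))
                dxpad[:, :, di : di + h, dj : dj + w] += np.tensordot(
                    dy, self.w[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        self.db[...] = dy.sum(axis=(0, 2, 3))
        self._xpad = None
        return dxpad[:, :, 1 : 1 + h, 1 : 1 + w]

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling; stores argmax indices for SegNet-style unpooling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self.indices = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self.indices[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.unpool(dy)

    def unpool(self, y: np.ndarray) -> np.ndarray:
        n, c, hh, ww = y.shape
        flat = np.zeros((n, c, hh, ww, 4), dtype=y.dtype)
        np.put_along_axis(flat, self.indices[..., None], y[..., None], axis=-1)
        return (
            flat.reshape(n, c, hh, ww, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, hh * 2, ww * 2)
        )


class MaxUnpool2:
    """Upsample with the paired pooling layer's stored indices."""

    def __init__(self, pool: MaxPool2):
        self.pool = pool

    def forward(self, x):
        return self.pool.unpool(x)

    def backward(self, dy):
        n, c, h, w = dy.shape
        flat = dy.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        return np.take_along_axis(flat, self.pool.indices[..., None], axis=-1)[..., 0]


def class_weights(labels: np.ndarray, n_classes: int = 10) -> np.ndarray:
    """Median-frequency balancing: w_c = median(freq)/freq_c over the classes
    present; absent classes get weight 0."""
    counts = np.bincount(np.asarray(labels).ravel(), minlength=n_classes).astype(float)
    freq = counts / counts.sum()
    present = freq > 0
    weights = np.zeros(n_classes)
    weights[present] = np.median(freq[present]) / freq[present]
    return weights


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray, weights=None):
    """Per-pixel cross entropy, optionally class-weighted; returns
    (loss, dlogits).  Loss is the weighted mean over pixels."""
    n, c, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    sel = (
        np.arange(n)[:, None, None],
        np.arange(h)[None, :, None],
        np.arange(w)[None, None, :],
        labels,
    )
    nll = -np.log(np.maximum(probs.transpose(0, 2, 3, 1)[sel], 1e-12))
    onehot = np.zeros_like(probs)
    onehot.transpose(0, 2, 3, 1)[sel] = 1.0
    if weights is None:
        loss = float(nll.mean())
        dlogits = (probs - onehot) / (n * h * w)
    else:
        wpix = np.asarray(weights, dtype=np.float64)[labels]  # (N,H,W)
        wsum = wpix.sum()
        loss = float((wpix * nll).sum() / wsum)
        dlogits = (probs - onehot) * (wpix / wsum)[:, None, :, :]
    return loss, dlogits.astype(np.float32)


@dataclass
class SegModelSpec:
    """Architecture hyperparameters for the desk-scale segmenter.

    ``in_channels`` counts the normalized intensity plus the coordinate
    channels (raw z/row/col plus their sin/cos Fourier encodings at four
    frequencies) appended so the translation-equivariant network can tell
    mirror-image and z-stacked structures apart.
    """

    in_channels: int = 28
    widths: tuple[int, int] = (32, 48)
    n_classes: int = 10


class SegNet2D:
    """Encoder-decoder network; output spatial shape equals input shape."""

    def __init__(self, spec: SegModelSpec | None = None, seed: int = 0):
        self.spec = spec or SegModelSpec()
        rng = np.random.default_rng(seed)
        w1, w2 = self.spec.widths
        self.enc1 = Conv3x3(self.spec.in_channels, w1, rng)
        self.enc2 = Conv3x3(w1, w2, rng)
        self.mid = Conv3x3(w2, w2, rng)
        self.dec2 = Conv3x3(w2, w1, rng)
        self.dec1 = Conv3x3(w1, w1, rng)
        self.head = Conv3x3(w1, self.spec.n_classes, rng)
        self.pool1, self.pool2 = MaxPool2(), MaxPool2()
        self.r = [ReLU() for _ in range(5)]
        self._convs = [self.enc1, self.enc2, self.mid, self.dec2, self.dec1, self.head]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError(f"spatial shape {x.shape[2:]} must be divisible by 4")
        h = self.r[0].forward(self.enc1.forward(x.astype(np.float32, copy=False)))
        h = self.pool1.forward(h)
        h = self.r[1].forward(self.enc2.forward(h))
        h = self.pool2.forward(h)
        h = self.r[2].forward(self.mid.forward(h))
        h = self.pool2.unpool(h)
        h = self.r[3].forward(self.dec2.forward(h))
        h = self.pool1.unpool(h)
        h = self.r[4].forward(self.dec1.forward(h))
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.dec1.backward(self.r[4].backward(d))
        d = MaxUnpool2(self.pool1).backward(d)
        d = self.dec2.backward(self.r[3].backward(d))
        d = MaxUnpool2(self.pool2).backward(d)
        d = self.mid.backward(self.r[2].backward(d))
        d = self.pool2.backward(d)
        d = self.enc2.backward(self.r[1].backward(d))
        d = self.pool1.backward(d)
        self.enc1.backward(self.r[0].backward(d))

    def params(self):
        out = []
        for conv in self._convs:
            out.extend(conv.params())
        return out

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for p, _ in self.params())

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_state(self, state) -> None:
        for (p, _), s in zip(self.params(), state):
            p[...] = s

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel label map(s) for a (N, C, H, W) input batch."""
        return self.forward(x).argmax(axis=1)


class Adam:
    """Adam with classic L2 weight decay folded into the gradient."""

    def __init__(self, params, lr: float = 1e-3, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            grad = g + self.weight_decay * p
            self.m[i] = b1 * self.m[i] + (1 - b1) * grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * grad * grad
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
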