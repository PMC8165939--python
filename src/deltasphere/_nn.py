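"""Minimal convolutional network with manual backpropagation.

A compact, fully deterministic numpy implementation sized for desk-scale
grayscale crops: a 1->3 channel adapter convolution (so the network accepts
single-channel microscopy images in an RGB-style trunk), three conv/ReLU/
max-pool blocks, global average pooling and a linear softmax head. Trained
with mini-batch Adam on the cross-entropy loss.

Convolutions are 3x3, stride 1, zero-padded ("same"), computed via im2col
and a single matrix multiply; pooling is 2x2 non-overlapping, so input
sides must be divisible by 8.
"""

from __future__ import annotations


import numpy as np


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*9) patch matrix for a padded 3x3 convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, c, h, w = shape
    d = dcols.reshape(n, h, w, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki : ki + h, kj : kj + w] += d[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1]


class Conv3x3:
    """3x3 same-padding convolution, stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, scale, size=(c_in * 9, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x)
        out = cols @ self.w + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, _, h, w = xshape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, -1)
        self.dw = cols.T @ dflat
        self.db = dflat.sum(axis=0)
        return _col2im(dflat @ self.w.T, xshape)

    @property
    def params(self):
        return [("w", self), ("b", self)]


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 non-overlapping max pool; sides must be even."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        self._arg = xr.argmax(axis=4)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=4)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=4)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )


class SmallCNN:
    """Adapter conv (1->3 ch) + three conv/ReLU/pool blocks + softmax head."""

    def __init__(self, n_classes: int = 2, seed: int = 0, channels=(8, 16, 32)):
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.adapter = Conv3x3(1, 3, rng)
        self.blocks = []
        c_prev = 3
        for c in channels:
            self.blocks.append((Conv3x3(c_prev, c, rng), ReLU(), MaxPool2()))
            c_prev = c
        self.fc_w = (rng.normal(0.0, np.sqrt(1.0 / c_prev), size=(c_prev, n_classes))).astype(
            np.float32
        )
        self.fc_b = np.zeros(n_classes, dtype=np.float32)
        self.n_classes = n_classes

    # ---- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Return softmax class probabilities for a (N, 1, H, W) batch."""
        x = np.asarray(x, dtype=np.float32)
        h = self.adapter.forward(x, train)
        for conv, relu, pool in self.blocks:
            h = pool.forward(relu.forward(conv.forward(h, train), train), train)
        feat = h.mean(axis=(2, 3))  # global average pool
        logits = feat @ self.fc_w + self.fc_b
        if train:
            self._feat = feat
            self._pool_shape = h.shape
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, probs: np.ndarray, y: np.ndarray) -> float:
        """Cross-entropy gradient pass; returns the mean batch loss."""
        n = len(y)
        loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        self.dfc_w = self._feat.T @ dlogits
        self.dfc_b = dlogits.sum(axis=0)
        dfeat = dlogits @ self.fc_w.T
        _, c, hh, ww = self._pool_shape
        dh = np.broadcast_to(dfeat[:, :, None, None] / (hh * ww), self._pool_shape).astype(
            np.float32
        )
        for conv, relu, pool in reversed(self.blocks):
            dh = conv.backward(relu.backward(pool.backward(dh)))
        self.adapter.backward(dh)
        return loss

    # ---- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        p = {"adapter.w": self.adapter.w, "adapter.b": self.adapter.b}
        for i, (conv, _, _) in enumerate(self.blocks):
            p[f"block{i}.w"] = conv.w
            p[f"block{i}.b"] = conv.b
        p["fc.w"] = self.fc_w
        p["fc.b"] = self.fc_b
        return p

    def gradients(self) -> dict[str, np.ndarray]:
        g = {"adapter.w": self.adapter.dw, "adapter.b": self.adapter.db}
        for i, (conv, _, _) in enumerate(self.blocks):
            g[f"block{i}.w"] = conv.dw
            g[f"block{i}.b"] = conv.db
        g["fc.w"] = self.dfc_w
        g["fc.b"] = self.dfc_b
        return g

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        self.adapter.w = params["adapter.w"].astype(np.float32).copy()
        self.adapter.b = params["adapter.b"].astype(np.float32).copy()
        for i, (conv, _, _) in enumerate(self.blocks):
            conv.w = params[f"block{i}.w"].astype(np.float32).copy()
            conv.b = params[f"block{i}.b"].astype(np.float32).copy()
        self.fc_w = params["fc.w"].astype(np.float32).copy()
        self.fc_b = params["fc.b"].astype(np.float32).copy()

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}


class Adam:
    """Standard Adam optimiser over a model's named parameters."""

    def __init__(self, model: SmallCNN, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        params = model.parameters()
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        params = self.model.parameters()
        grads = self.model.gradients()
        bc1 = 1 - self.beta1**self.t
        bc2 = 1 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k].astype(p.dtype)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def resize_bilinear(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Fast bilinear resize of a single 2-D image (align-corners=False)."""
    h, w = img.shape
    oh, ow = out_hw
    if (h, w) == (oh, ow):
        return img.copy()
    ry = (np.arange(oh) + 0.5) * h / oh - 0.5
    rx = (np.arange(ow) + 0.5) * w / ow - 0.5
    y0 = np.clip(np.floor(ry).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(rx).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    fy = np.clip(ry - y0, 0.0, 1.0)[:, None]
    fx = np.clip(rx - x0, 0.0, 1.0)[None, :]
    a = img[np.ix_(y0, x0)]
    b = img[np.ix_(y0, x1)]
    c = img[np.ix_(y1, x0)]
    d = img[np.ix_(y1, x1)]
    return ((a * (1 - fx) + b * fx) * (1 - fy) + (c * (1 - fx) + d * fx) * fy).astype(img.dtype)
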