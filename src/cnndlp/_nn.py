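"""Minimal neural-network layers with explicit forward/backward passes.

Everything the dual-branch scorer needs, implemented on numpy: stride-1
"same-ish" convolution (one ring of zero padding, valid convolution),
transpose convolution as the exact adjoint of that operation, 2x2
max-pooling in ceil mode with recorded argmax positions, max-unpooling that
scatters back into the recorded pre-pool shape, batch normalization,
dropout, dense layers and the per-entry tanh attention head.

Layers cache what their backward pass needs; ``backward`` consumes the
upstream gradient and populates ``grads`` aligned with ``params``. All
gradients are verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d",
    "Conv",
    "TransposeConv",
    "ReLU",
    "BatchNorm",
    "MaxPool",
    "MaxUnpool",
    "Flatten",
    "Dropout",
    "Dense",
    "Attention",
    "softmax",
    "softmax_xent",
    "Adam",
]


def _im2col(x: np.ndarray, kh: int, kw: int) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Unfold (B,C,H,W) into (B*Ho*Wo, C*kh*kw) patch rows."""
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))
    b, c, ho, wo = win.shape[:4]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * kh * kw)
    return col, (b, ho, wo)


def conv2d(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Valid stride-1 cross-correlation. x: (B,C,H,W); W: (F,C,kh,kw).

    Implemented as im2col + one matmul; at the small feature-map sizes this
    model uses, that is far faster than a windowed einsum.
    """
    col, (b, ho, wo) = _im2col(x, W.shape[2], W.shape[3])
    out = col @ W.reshape(W.shape[0], -1).T
    return out.reshape(b, ho, wo, -1).transpose(0, 3, 1, 2)


def _conv2d_wgrad(col: np.ndarray, g: np.ndarray, shape: tuple) -> np.ndarray:
    """Gradient of conv2d w.r.t. its kernel from the cached im2col rows."""
    f = g.shape[1]
    gcol = g.transpose(0, 2, 3, 1).reshape(-1, f)
    return (col.T @ gcol).T.reshape(shape)


def _pad(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv(Layer):
    """Zero-pad one ring, then valid 2D convolution: (H, W) -> (H+3-kh, W+3-kw)."""

    def __init__(self, cin: int, cout: int, k: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        kh, kw = k
        scale = 1.0 / np.sqrt(cin * kh * kw)
        self.W = rng.normal(0.0, scale, size=(cout, cin, kh, kw))
        self.b = np.zeros(cout)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        kh, kw = self.W.shape[2:]
        if x.shape[2] + 2 < kh or x.shape[3] + 2 < kw:
            raise ValueError("input smaller than convolution window after padding")
        xp = _pad(x, 1, 1)
        self._col, (b, ho, wo) = _im2col(xp, kh, kw)
        out = self._col @ self.W.reshape(self.W.shape[0], -1).T
        return out.reshape(b, ho, wo, -1).transpose(0, 3, 1, 2) + self.b[None, :, None, None]

    def backward(self, g):
        kh, kw = self.W.shape[2:]
        self.grads[0][...] = _conv2d_wgrad(self._col, g, self.W.shape)
        self.grads[1][...] = g.sum(axis=(0, 2, 3))
        Wt = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        gxp = conv2d(_pad(g, kh - 1, kw - 1), Wt)
        return gxp[:, :, 1:-1, 1:-1]


class TransposeConv(Layer):
    """Exact adjoint of :class:`Conv` (its backward-input map), plus a bias.

    Maps (H, W) -> (H+kh-3, W+kw-3), undoing the spatial growth of the
    padded convolution it mirrors.
    """

    def __init__(self, cin: int, cout: int, k: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        kh, kw = k
        scale = 1.0 / np.sqrt(cin * kh * kw)
        # Stored as the kernel of the mirrored forward conv (cin <- cout).
        self.W = rng.normal(0.0, scale, size=(cin, cout, kh, kw))
        self.b = np.zeros(cout)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        kh, kw = self.W.shape[2:]
        self._x = x
        Wt = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (cout, cin, kh, kw)
        y_full = conv2d(_pad(x, kh - 1, kw - 1), Wt)
        return y_full[:, :, 1:-1, 1:-1] + self.b[None, :, None, None]

    def backward(self, g):
        kh, kw = self.W.shape[2:]
        self.grads[1][...] = g.sum(axis=(0, 2, 3))
        g_full = _pad(g, 1, 1)
        xp = _pad(self._x, kh - 1, kw - 1)
        col, _ = _im2col(xp, kh, kw)
        cout, cin = g.shape[1], self._x.shape[1]
        gWt = _conv2d_wgrad(col, g_full, (cout, cin, kh, kw))
        self.grads[0][...] = gWt.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        return conv2d(g_full, self.W)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return g * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, height, width)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self._collect: list | None = None

    def start_collect(self) -> None:
        """Begin collecting batch statistics instead of running updates."""
        self._collect = []

    def finish_collect(self) -> None:
        """Set the running statistics to the pooled collected values."""
        if not self._collect:
            self._collect = None
            return
        means = np.array([m for m, _, _ in self._collect])
        variances = np.array([v for _, v, _ in self._collect])
        weights = np.array([n for _, _, n in self._collect], float)
        w = weights[:, None] / weights.sum()
        mean = (w * means).sum(axis=0)
        # law of total variance across batches
        self.run_var = (w * (variances + means**2)).sum(axis=0) - mean**2
        self.run_mean = mean
        self._collect = None

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self._collect is not None:
                n = x.shape[0] * x.shape[2] * x.shape[3]
                self._collect.append((mean, var, n))
            else:
                self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
                self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        self._train = train
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, g):
        axes = (0, 2, 3)
        self.grads[0][...] = (g * self._xhat).sum(axis=axes)
        self.grads[1][...] = g.sum(axis=axes)
        gx_hat = g * self.gamma[None, :, None, None]
        if not self._train:
            return gx_hat / self._std
        return (
            gx_hat
            - gx_hat.mean(axis=axes, keepdims=True)
            - self._xhat * (gx_hat * self._xhat).mean(axis=axes, keepdims=True)
        ) / self._std


class MaxPool(Layer):
    """2x2 max pooling, stride 2, ceil mode (partial windows kept).

    Records the within-window argmax so a paired :class:`MaxUnpool` can
    scatter values back to their original positions.
    """

    def forward(self, x, train):
        B, C, H, W = x.shape
        Ho, Wo = -(-H // 2), -(-W // 2)
        xp = np.full((B, C, Ho * 2, Wo * 2), -np.inf)
        xp[:, :, :H, :W] = x
        r = (
            xp.reshape(B, C, Ho, 2, Wo, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, Ho, Wo, 4)
        )
        self.idx = r.argmax(axis=-1)
        self.in_shape = (H, W)
        return np.take_along_axis(r, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        return _scatter(g, self.idx, self.in_shape)


class MaxUnpool(Layer):
    """Scatter pooled values back using a paired pool's recorded argmax."""

    def __init__(self, pool: MaxPool):
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        return _scatter(x, self.pool.idx, self.pool.in_shape)

    def backward(self, g):
        return _gather(g, self.pool.idx)


def _scatter(vals: np.ndarray, idx: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    B, C, Ho, Wo = vals.shape
    H, W = shape
    out = np.zeros((B, C, Ho, Wo, 4))
    np.put_along_axis(out, idx[..., None], vals[..., None], axis=-1)
    out = (
        out.reshape(B, C, Ho, Wo, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(B, C, Ho * 2, Wo * 2)
    )
    return out[:, :, :H, :W]


def _gather(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    B, C, Ho, Wo = idx.shape
    xp = np.zeros((B, C, Ho * 2, Wo * 2))
    xp[:, :, : x.shape[2], : x.shape[3]] = x
    r = (
        xp.reshape(B, C, Ho, 2, Wo, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(B, C, Ho, Wo, 4)
    )
    return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class Attention(Layer):
    """Per-entry adjacent-edge attention.

    Each scalar embedding entry x is projected to a d_att vector
    F = tanh(w*x + b); its score s = F.u is softmax-normalized over all
    columns of the entry's row (all adjacent edges of that node), and the
    output is alpha * x.
    """

    def __init__(self, d_att: int, rng: np.random.Generator):
        super().__init__()
        if d_att < 1:
            raise ValueError("d_att must be >= 1")
        self.w = rng.normal(0.0, 0.5, size=d_att)
        self.b = np.zeros(d_att)
        self.u = rng.normal(0.0, 0.5, size=d_att)
        self.params = [self.w, self.b, self.u]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train):
        # x: (B, 2, N)
        for p in self.params:
            if not np.isfinite(p).all():
                raise ValueError("non-finite attention parameters")
        self._x = x
        self._F = np.tanh(x[..., None] * self.w + self.b)
        s = self._F @ self.u
        self._alpha = softmax(s, axis=-1)
        return self._alpha * x

    def backward(self, g):
        x, F, alpha = self._x, self._F, self._alpha
        g_alpha = g * x
        gs = alpha * (g_alpha - (g_alpha * alpha).sum(axis=-1, keepdims=True))
        sech2 = 1.0 - F**2
        core = gs[..., None] * sech2 * self.u  # dL/d(w*x+b) per component
        self.grads[0][...] = (core * x[..., None]).sum(axis=(0, 1, 2))
        self.grads[1][...] = core.sum(axis=(0, 1, 2))
        self.grads[2][...] = (gs[..., None] * F).sum(axis=(0, 1, 2))
        ds_dx = (sech2 * (self.w * self.u)).sum(axis=-1)
        return g * alpha + gs * ds_dx


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray]:
    """Two-class softmax + mean cross-entropy.

    Returns (class-1 probabilities, mean loss, gradient w.r.t. logits).
    """
    p = softmax(logits, axis=-1)
    onehot = np.zeros_like(p)
    onehot[np.arange(len(labels)), labels.astype(int)] = 1.0
    eps = 1e-12
    loss = -np.log(np.clip((p * onehot).sum(axis=-1), eps, None)).mean()
    grad = (p - onehot) / len(labels)
    return p[:, 1], float(loss), grad


class Adam:
    """Adam over a flat list of (param, grad) pairs."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.pairs = [
            (p, g) for layer in layers for p, g in zip(layer.params, layer.grads)
        ]
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
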