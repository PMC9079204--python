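"""Minimal NHWC neural-network layers with explicit forward/backward passes.

All image tensors are ``(batch, height, width, channels)`` float arrays.
Convolutions are computed as a sum of kernel-offset-shifted batched matrix
products, which avoids the memory blow-up of im2col and is the fastest
pure-NumPy strategy for the small channel counts used here. Every layer
caches what its backward pass needs during ``forward(..., training=True)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "DepthwiseConv2D",
    "Dense",
    "ReLU",
    "AvgPool2D",
    "MaxPool2D",
    "GlobalAvgPool",
    "BatchNorm",
    "Flatten",
    "Dropout",
    "Softmax",
    "Add",
    "Concat",
    "PadChannels",
    "RepeatChannels",
]


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int]:
    """TensorFlow-style 'same' padding amounts (before, after) for one axis."""
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + kernel - size, 0)
    before = total // 2
    return before, total - before


def he_uniform(shape, fan_in, rng, dtype):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: holds trainable parameters and their gradients."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x, training=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    """2-D convolution (cross-correlation), NHWC, arbitrary kernel/stride.

    Weights have shape ``(kh, kw, in_ch, out_ch)``; He-uniform initialised.
    """

    def __init__(self, in_ch, out_ch, kernel=(3, 3), stride=1, padding="same",
                 bias=True, rng=None, dtype=np.float32):
        super().__init__()
        if isinstance(kernel, int):
            kernel = (kernel, kernel)
        self.kh, self.kw = kernel
        self.stride = int(stride)
        self.padding = padding
        self.in_ch, self.out_ch = int(in_ch), int(out_ch)
        rng = rng or np.random.default_rng()
        fan_in = self.kh * self.kw * in_ch
        self.W = he_uniform((self.kh, self.kw, in_ch, out_ch), fan_in, rng, dtype)
        self.params = [self.W]
        self.use_bias = bias
        if bias:
            self.b = np.zeros(out_ch, dtype=dtype)
            self.params.append(self.b)
        self.grads = [np.zeros_like(p) for p in self.params]

    def _pad_amounts(self, h, w):
        if self.padding == "same":
            return _same_pad(h, self.kh, self.stride), _same_pad(w, self.kw, self.stride)
        return (0, 0), (0, 0)

    @property
    def _fast(self):
        # stride-1 'same' odd-kernel convs (the hot path) use full-array
        # GEMMs with shifted accumulation instead of padded slicing
        return (self.stride == 1 and self.padding == "same"
                and self.kh % 2 == 1 and self.kw % 2 == 1)

    @staticmethod
    def _shift_ranges(d, n):
        # dst[a0:a1] aligns with src[c0:c1] for an offset of d
        return max(0, -d), n - max(0, d), max(0, d), n + min(0, d)

    def _scratch(self, shape, dtype, key):
        buf = getattr(self, key, None)
        if buf is None or buf.shape != shape or buf.dtype != dtype:
            buf = np.empty(shape, dtype=dtype)
            setattr(self, key, buf)
        return buf

    def _forward_fast(self, x, training):
        B, H, W, C = x.shape
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        xf = np.ascontiguousarray(x).reshape(-1, C)
        y = np.zeros((B, H, W, self.out_ch), dtype=x.dtype)
        tf = self._scratch((xf.shape[0], self.out_ch), x.dtype, "_buf_f")
        t = tf.reshape(B, H, W, self.out_ch)
        for i in range(self.kh):
            a0, a1, c0, c1 = self._shift_ranges(i - ph, H)
            for j in range(self.kw):
                b0, b1, d0, d1 = self._shift_ranges(j - pw, W)
                np.matmul(xf, self.W[i, j], out=tf)
                y[:, a0:a1, b0:b1] += t[:, c0:c1, d0:d1]
        if self.use_bias:
            y += self.b
        if training:
            self._x = x
        return y

    def _backward_fast(self, dy):
        x = self._x
        B, H, W, C = x.shape
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        dyf = np.ascontiguousarray(dy).reshape(-1, self.out_ch)
        dW = self.grads[0]
        dW[...] = 0.0
        dx = np.zeros_like(x)
        tf = self._scratch((dyf.shape[0], C), dy.dtype, "_buf_b")
        t = tf.reshape(B, H, W, C)
        for i in range(self.kh):
            a0, a1, c0, c1 = self._shift_ranges(i - ph, H)
            for j in range(self.kw):
                b0, b1, d0, d1 = self._shift_ranges(j - pw, W)
                np.matmul(dyf, self.W[i, j].T, out=tf)
                dx[:, c0:c1, d0:d1] += t[:, a0:a1, b0:b1]
                xs = x[:, c0:c1, d0:d1]
                ys = dy[:, a0:a1, b0:b1]
                dW[i, j] += np.matmul(xs.swapaxes(-1, -2), ys).sum(axis=(0, 1))
        if self.use_bias:
            self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        return dx

    def forward(self, x, training=False):
        if self._fast:
            return self._forward_fast(x, training)
        s = self.stride
        B, H, W, C = x.shape
        (pt, pb), (pl, pr) = self._pad_amounts(H, W)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))) if (pt | pb | pl | pr) else x
        Hp, Wp = xp.shape[1:3]
        OH = (Hp - self.kh) // s + 1
        OW = (Wp - self.kw) // s + 1
        y = np.zeros((B, OH, OW, self.out_ch), dtype=xp.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                xs = xp[:, i : i + s * (OH - 1) + 1 : s, j : j + s * (OW - 1) + 1 : s, :]
                y += xs @ self.W[i, j]
        if self.use_bias:
            y += self.b
        if training:
            self._xp = xp
            self._pads = (pt, pl)
            self._xshape = x.shape
        return y

    def backward(self, dy):
        if self._fast:
            return self._backward_fast(dy)
        s = self.stride
        xp = self._xp
        B, OH, OW, F = dy.shape
        dW, db = self.grads[0], (self.grads[1] if self.use_bias else None)
        dW[...] = 0.0
        dxp = np.zeros_like(xp)
        for i in range(self.kh):
            for j in range(self.kw):
                sl = np.s_[:, i : i + s * (OH - 1) + 1 : s, j : j + s * (OW - 1) + 1 : s, :]
                xs = xp[sl]
                # (B,OH,C,OW) @ (B,OH,OW,F) -> (B,OH,C,F), summed over batch rows
                dW[i, j] += np.matmul(xs.swapaxes(-1, -2), dy).sum(axis=(0, 1))
                dxp[sl] += dy @ self.W[i, j].T
        if self.use_bias:
            db[...] = dy.sum(axis=(0, 1, 2))
        pt, pl = self._pads
        Bx, H, W, C = self._xshape
        return dxp[:, pt : pt + H, pl : pl + W, :]


class DepthwiseConv2D(Layer):
    """Depthwise 3x3-style convolution (depth multiplier 1), NHWC."""

    def __init__(self, in_ch, kernel=(3, 3), stride=1, padding="same",
                 bias=False, rng=None, dtype=np.float32):
        super().__init__()
        if isinstance(kernel, int):
            kernel = (kernel, kernel)
        self.kh, self.kw = kernel
        self.stride = int(stride)
        self.padding = padding
        self.in_ch = int(in_ch)
        rng = rng or np.random.default_rng()
        fan_in = self.kh * self.kw
        self.W = he_uniform((self.kh, self.kw, in_ch), fan_in, rng, dtype)
        self.params = [self.W]
        self.use_bias = bias
        if bias:
            self.b = np.zeros(in_ch, dtype=dtype)
            self.params.append(self.b)
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training=False):
        s = self.stride
        B, H, W, C = x.shape
        if self.padding == "same":
            (pt, pb) = _same_pad(H, self.kh, s)
            (pl, pr) = _same_pad(W, self.kw, s)
        else:
            pt = pb = pl = pr = 0
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))) if (pt | pb | pl | pr) else x
        Hp, Wp = xp.shape[1:3]
        OH = (Hp - self.kh) // s + 1
        OW = (Wp - self.kw) // s + 1
        y = np.zeros((B, OH, OW, C), dtype=xp.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                xs = xp[:, i : i + s * (OH - 1) + 1 : s, j : j + s * (OW - 1) + 1 : s, :]
                y += xs * self.W[i, j]
        if self.use_bias:
            y += self.b
        if training:
            self._xp, self._pads, self._xshape = xp, (pt, pl), x.shape
        return y

    def backward(self, dy):
        s = self.stride
        xp = self._xp
        B, OH, OW, C = dy.shape
        dW = self.grads[0]
        dW[...] = 0.0
        dxp = np.zeros_like(xp)
        for i in range(self.kh):
            for j in range(self.kw):
                sl = np.s_[:, i : i + s * (OH - 1) + 1 : s, j : j + s * (OW - 1) + 1 : s, :]
                dW[i, j] += (xp[sl] * dy).sum(axis=(0, 1, 2))
                dxp[sl] += dy * self.W[i, j]
        if self.use_bias:
            self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        pt, pl = self._pads
        _, H, W, _ = self._xshape
        return dxp[:, pt : pt + H, pl : pl + W, :]


class Dense(Layer):
    def __init__(self, in_dim, out_dim, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.W = he_uniform((in_dim, out_dim), in_dim, rng, dtype)
        self.params = [self.W]
        self.use_bias = bias
        if bias:
            self.b = np.zeros(out_dim, dtype=dtype)
            self.params.append(self.b)
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training=False):
        if training:
            self._x = x
        y = x @ self.W
        if self.use_bias:
            y += self.b
        return y

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        if self.use_bias:
            self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x, training=False):
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class AvgPool2D(Layer):
    """Average pooling, 'valid', arbitrary kernel and stride (incl. stride 1)."""

    def __init__(self, pool=2, stride=2):
        super().__init__()
        self.k = int(pool)
        self.stride = int(stride)

    def forward(self, x, training=False):
        k, s = self.k, self.stride
        B, H, W, C = x.shape
        OH = (H - k) // s + 1
        OW = (W - k) // s + 1
        y = np.zeros((B, OH, OW, C), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                y += x[:, i : i + s * (OH - 1) + 1 : s, j : j + s * (OW - 1) + 1 : s, :]
        y /= k * k
        if training:
            self._xshape = x.shape
        return y

    def backward(self, dy):
        k, s = self.k, self.stride
        B, OH, OW, C = dy.shape
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        g = dy / (k * k)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + s * (OH - 1) + 1 : s, j : j + s * (OW - 1) + 1 : s, :] += g
        return dx


class MaxPool2D(Layer):
    """Max pooling with optional 'same' padding (ties routed to first maximum)."""

    def __init__(self, pool=2, stride=2, padding="valid"):
        super().__init__()
        self.k = int(pool)
        self.stride = int(stride)
        self.padding = padding

    def forward(self, x, training=False):
        k, s = self.k, self.stride
        B, H, W, C = x.shape
        if self.padding == "same":
            (pt, pb) = _same_pad(H, k, s)
            (pl, pr) = _same_pad(W, k, s)
            xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)),
                        constant_values=-np.inf)
        else:
            pt = pl = 0
            xp = x
        Hp, Wp = xp.shape[1:3]
        OH = (Hp - k) // s + 1
        OW = (Wp - k) // s + 1
        stack = np.stack(
            [xp[:, i : i + s * (OH - 1) + 1 : s, j : j + s * (OW - 1) + 1 : s, :]
             for i in range(k) for j in range(k)],
            axis=-1,
        )
        idx = stack.argmax(axis=-1)
        y = np.take_along_axis(stack, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx = idx
            self._pads = (pt, pl)
            self._xpshape = xp.shape
            self._xshape = x.shape
        return y

    def backward(self, dy):
        k, s = self.k, self.stride
        B, OH, OW, C = dy.shape
        dxp = np.zeros(self._xpshape, dtype=dy.dtype)
        n = 0
        for i in range(k):
            for j in range(k):
                sl = np.s_[:, i : i + s * (OH - 1) + 1 : s, j : j + s * (OW - 1) + 1 : s, :]
                dxp[sl] += dy * (self._idx == n)
                n += 1
        pt, pl = self._pads
        _, H, W, _ = self._xshape
        return dxp[:, pt : pt + H, pl : pl + W, :]


class GlobalAvgPool(Layer):
    def forward(self, x, training=False):
        if training:
            self._xshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        B, H, W, C = self._xshape
        return np.broadcast_to(dy[:, None, None, :] / (H * W), self._xshape).copy()


class BatchNorm(Layer):
    """Per-channel batch normalisation over (B, H, W) with running statistics."""

    def __init__(self, ch, momentum=0.99, eps=1e-3, dtype=np.float32):
        super().__init__()
        self.gamma = np.ones(ch, dtype=dtype)
        self.beta = np.zeros(ch, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * invstd
            self._xhat, self._invstd, self._axes = xhat, invstd, axes
            self._n = x.size // x.shape[-1]
            return self.gamma * xhat + self.beta
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * (x - self.running_mean) * invstd + self.beta

    def backward(self, dy):
        xhat, invstd, axes, n = self._xhat, self._invstd, self._axes, self._n
        self.grads[0][...] = (dy * xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        return (invstd / n) * (
            n * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )


class Flatten(Layer):
    def forward(self, x, training=False):
        if training:
            self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._xshape)


class Dropout(Layer):
    """Inverted dropout; active only during training. Seed via ``reseed``."""

    def __init__(self, rate=0.2, seed=0):
        super().__init__()
        self.rate = float(rate)
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed):
        self.rng = np.random.default_rng(seed)

    def forward(self, x, training=False):
        if not training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask.astype(x.dtype)

    def backward(self, dy):
        if self.rate <= 0.0:
            return dy
        return dy * self._mask.astype(dy.dtype)


class Softmax(Layer):
    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        if training:
            self._p = p
        return p

    def backward(self, dy):
        p = self._p
        return p * (dy - (dy * p).sum(axis=-1, keepdims=True))


class Add(Layer):
    """Elementwise sum of two inputs (the residual merge)."""

    def forward(self, a, b, training=False):
        return a + b

    def backward(self, dy):
        return dy, dy


class Concat(Layer):
    """Channel-axis concatenation of any number of inputs."""

    def forward(self, *xs, training=False):
        if training:
            self._sizes = [x.shape[-1] for x in xs]
        return np.concatenate(xs, axis=-1)

    def backward(self, dy):
        splits = np.cumsum(self._sizes)[:-1]
        return tuple(np.split(dy, splits, axis=-1))


class PadChannels(Layer):
    """Parameter-free projection: zero-pad the channel axis by ``extra``."""

    def __init__(self, extra):
        super().__init__()
        self.extra = int(extra)

    def forward(self, x, training=False):
        if self.extra == 0:
            return x
        pad = [(0, 0)] * (x.ndim - 1) + [(0, self.extra)]
        return np.pad(x, pad)

    def backward(self, dy):
        if self.extra == 0:
            return dy
        return dy[..., : dy.shape[-1] - self.extra]


class RepeatChannels(Layer):
    """Replicate a single-channel image across ``n`` channels (grayscale->RGB)."""

    def __init__(self, n=3):
        super().__init__()
        self.n = int(n)

    def forward(self, x, training=False):
        return np.repeat(x, self.n, axis=-1)

    def backward(self, dy):
        B, H, W, C = dy.shape
        return dy.reshape(B, H, W, C // self.n, self.n).sum(axis=-1)
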