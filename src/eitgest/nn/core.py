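"""Minimal feed-forward/recurrent layer library with explicit backprop.

Array layout is channels-first: feature maps are ``(B, C, H, W)`` and
sequences ``(B, T, D)``, float32.  Every layer implements ``forward`` and
``backward`` (returning the gradient w.r.t. its input and accumulating
parameter gradients), which keeps the training loop a plain SGD/Adam
update.  Gradients are validated against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self):
        return []

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(DTYPE)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng):
        self.W = Param(_glorot(rng, (d_in, d_out), d_in, d_out), "W")
        self.b = Param(np.zeros(d_out), "b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g):
        self.W.grad += self._x.reshape(-1, self._x.shape[-1]).T @ g.reshape(-1, g.shape[-1])
        self.b.grad += g.reshape(-1, g.shape[-1]).sum(axis=0)
        return g @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Conv2d(Layer):
    """2-D convolution with 'same' zero padding and optional dilation.

    Implemented as a sum over kernel taps of shifted views, which maps
    onto large matmuls and avoids explicit im2col buffers.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng, dilation: int = 1):
        fan_in = c_in * kernel * kernel
        self.W = Param(_glorot(rng, (c_out, c_in, kernel, kernel), fan_in, c_out), "W")
        self.b = Param(np.zeros(c_out), "b")
        self.kernel = kernel
        self.dilation = dilation
        self.pad = dilation * (kernel - 1) // 2

    def params(self):
        return [self.W, self.b]

    def _w2(self):
        # (C_out, k*k*C_in), tap-major to match the patch stacking below
        return self.W.value.transpose(0, 2, 3, 1).reshape(self.W.value.shape[0], -1)

    def forward(self, x, train=False):
        B, C, H, Wd = x.shape
        p = self.pad
        if p:
            xp = np.zeros((B, C, H + 2 * p, Wd + 2 * p), dtype=x.dtype)
            xp[:, :, p : p + H, p : p + Wd] = x
        else:
            xp = x
        self._xp_shape = xp.shape
        k, d = self.kernel, self.dilation
        # one big GEMM: (C_out, k*k*C) @ (k*k*C, B*H*W)
        P = np.empty((k * k, C, B, H * Wd), dtype=x.dtype)
        for ki in range(k):
            for kj in range(k):
                patch = xp[:, :, ki * d : ki * d + H, kj * d : kj * d + Wd]
                P[ki * k + kj] = patch.transpose(1, 0, 2, 3).reshape(C, B, H * Wd)
        P = P.reshape(k * k * C, B * H * Wd)
        self._P = P
        out = self._w2() @ P  # (C_out, B*H*W)
        c_out = out.shape[0]
        out = out.reshape(c_out, B, H, Wd).transpose(1, 0, 2, 3)
        out = out + self.b.value[None, :, None, None]
        self._in_shape = x.shape
        return out

    def backward(self, g):
        B, C, H, Wd = self._in_shape
        k, d, p = self.kernel, self.dilation, self.pad
        c_out = g.shape[1]
        gf = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(c_out, B * H * Wd)
        gW2 = gf @ self._P.T
        self.W.grad += gW2.reshape(c_out, k, k, C).transpose(0, 3, 1, 2)
        self.b.grad += gf.sum(axis=1)
        gP = (self._w2().T @ gf).reshape(k * k, C, B, H, Wd)
        gx = np.zeros(self._xp_shape, dtype=g.dtype)
        for ki in range(k):
            for kj in range(k):
                gx[:, :, ki * d : ki * d + H, kj * d : kj * d + Wd] += gP[
                    ki * k + kj
                ].transpose(1, 0, 2, 3)
        if p:
            gx = gx[:, :, p : p + H, p : p + Wd]
        return gx


class BilinearUpsample2x(Layer):
    """Factor-2 bilinear upsampling via separable interpolation matrices."""

    def __init__(self, size: int):
        U = np.zeros((2 * size, size), dtype=DTYPE)
        # align_corners=False convention: output pixel centres at
        # (j + 0.5)/2 - 0.5 in input coordinates, edges clamped.
        for j in range(2 * size):
            src = (j + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            w1 = src - i0
            i0c, i1c = np.clip(i0, 0, size - 1), np.clip(i0 + 1, 0, size - 1)
            U[j, i0c] += 1.0 - w1
            U[j, i1c] += w1
        self.U = U

    def forward(self, x, train=False):
        return np.matmul(np.matmul(self.U, x), self.U.T)

    def backward(self, g):
        return np.matmul(np.matmul(self.U.T, g), self.U)


def fold2x2(x: np.ndarray) -> np.ndarray:
    """Space-to-depth: 2x2 blocks become 4 channels (bijective, no arithmetic).

    ``(B, C, H, W) -> (B, 4C, H/2, W/2)``; block-local offsets map to the
    channel groups ``[C*(2*di+dj) : ...]`` so relative positions are kept.
    """
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("fold requires even spatial dimensions")
    x = x.reshape(B, C, H // 2, 2, W // 2, 2)
    return x.transpose(0, 3, 5, 1, 2, 4).reshape(B, 4 * C, H // 2, W // 2)


def unfold2x2(x: np.ndarray) -> np.ndarray:
    """Depth-to-space, exact inverse of :func:`fold2x2`."""
    B, C4, h, w = x.shape
    if C4 % 4:
        raise ValueError("unfold requires channel count divisible by 4")
    C = C4 // 4
    x = x.reshape(B, 2, 2, C, h, w)
    return x.transpose(0, 3, 4, 1, 5, 2).reshape(B, C, 2 * h, 2 * w)


class Fold(Layer):
    def forward(self, x, train=False):
        return fold2x2(x)

    def backward(self, g):
        return unfold2x2(g)


class Unfold(Layer):
    def forward(self, x, train=False):
        return unfold2x2(x)

    def backward(self, g):
        return fold2x2(g)


class AvgPool2d(Layer):
    """Non-overlapping average pooling (window = stride)."""

    def __init__(self, window: int):
        self.window = window

    def forward(self, x, train=False):
        w = self.window
        B, C, H, W = x.shape
        self._in_shape = x.shape
        return x.reshape(B, C, H // w, w, W // w, w).mean(axis=(3, 5))

    def backward(self, g):
        w = self.window
        B, C, H, W = self._in_shape
        g = g[:, :, :, None, :, None] / (w * w)
        return np.broadcast_to(
            g, (B, C, H // w, w, W // w, w)
        ).reshape(B, C, H, W)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class GRU(Layer):
    """Single-layer unidirectional GRU returning the final hidden state.

    Gates: ``z = sig(xWz + hUz + bz)``, ``r = sig(xWr + hUr + br)``,
    ``n = tanh(xWn + r*(hUn) + bn)``, ``h' = (1-z)*n + z*h``.  One bias
    per gate, so the parameter count is ``3*H*(D + H + 1)``.
    """

    def __init__(self, d_in: int, d_hidden: int, rng):
        D, H = d_in, d_hidden
        self.W = Param(_glorot(rng, (D, 3 * H), D, H), "W")
        self.U = Param(_glorot(rng, (H, 3 * H), H, H), "U")
        self.b = Param(np.zeros(3 * H), "b")
        self.H = H

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, x, train=False):
        B, T, D = x.shape
        H = self.H
        h = np.zeros((B, H), dtype=DTYPE)
        self._x = x
        self._steps = []
        for t in range(T):
            xt = x[:, t]
            gx = xt @ self.W.value + self.b.value
            gh = h @ self.U.value
            z = _sigmoid(gx[:, :H] + gh[:, :H])
            r = _sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
            q = gh[:, 2 * H :]
            n = np.tanh(gx[:, 2 * H :] + r * q)
            h_new = (1.0 - z) * n + z * h
            self._steps.append((h, z, r, q, n))
            h = h_new
        self._hT = h
        return h

    def backward(self, g):
        B, T, D = self._x.shape
        H = self.H
        gx_all = np.zeros((B, T, 3 * H), dtype=DTYPE)
        dh = g.astype(DTYPE)
        for t in range(T - 1, -1, -1):
            h_prev, z, r, q, n = self._steps[t]
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dan = dn * (1.0 - n * n)
            dr = dan * q
            dq = dan * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            gh_grad = np.concatenate([dz_pre, dr_pre, dq], axis=1)
            dh_prev = dh_prev + gh_grad @ self.U.value.T
            self.U.grad += h_prev.T @ gh_grad
            gx_grad = np.concatenate([dz_pre, dr_pre, dan], axis=1)
            gx_all[:, t] = gx_grad
            dh = dh_prev
        flat = gx_all.reshape(B * T, 3 * H)
        self.W.grad += self._x.reshape(B * T, D).T @ flat
        self.b.grad += flat.sum(axis=0)
        return (gx_all @ self.W.value.T).reshape(B, T, D)


class LSTM(Layer):
    """Single-layer unidirectional LSTM returning the final hidden state.

    One bias per gate: parameter count ``4*H*(D + H + 1)``; the forget
    gate bias is initialised to 1.
    """

    def __init__(self, d_in: int, d_hidden: int, rng):
        D, H = d_in, d_hidden
        self.W = Param(_glorot(rng, (D, 4 * H), D, H), "W")
        self.U = Param(_glorot(rng, (H, 4 * H), H, H), "U")
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0
        self.b = Param(b, "b")
        self.H = H

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, x, train=False):
        B, T, D = x.shape
        H = self.H
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        self._x = x
        self._steps = []
        for t in range(T):
            a = x[:, t] @ self.W.value + h @ self.U.value + self.b.value
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            o = _sigmoid(a[:, 2 * H : 3 * H])
            gc = np.tanh(a[:, 3 * H :])
            c_new = f * c + i * gc
            tc = np.tanh(c_new)
            self._steps.append((h, c, i, f, o, gc, tc))
            h = o * tc
            c = c_new
        return h

    def backward(self, g):
        B, T, D = self._x.shape
        H = self.H
        ga_all = np.zeros((B, T, 4 * H), dtype=DTYPE)
        dh = g.astype(DTYPE)
        dc = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, o, gc, tc = self._steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * gc
            df = dc * c_prev
            dgc = dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                    dgc * (1.0 - gc * gc),
                ],
                axis=1,
            )
            ga_all[:, t] = da
            dh = da @ self.U.value.T
            self.U.grad += h_prev.T @ da
            dc = dc * f
        flat = ga_all.reshape(B * T, 4 * H)
        self.W.grad += self._x.reshape(B * T, D).T @ flat
        self.b.grad += flat.sum(axis=0)
        return (ga_all @ self.W.value.T).reshape(B, T, D)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy of integer labels; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(DTYPE).tiny
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dl = p.copy()
    dl[np.arange(n), y] -= 1.0
    return float(loss), (dl / n).astype(DTYPE)


class Adam:
    """Adam optimiser over a list of :class:`Param`."""

    def __init__(self, params, lr=5e-5, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[:] = 0.0
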