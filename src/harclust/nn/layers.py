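"""Minimal trainable neural-network layers on numpy.

Implements exactly the layer vocabulary the feature-extractor family needs
(dense, 1-D/2-D convolution, max-pooling, batch normalization, dropout,
LSTM / bidirectional LSTM, and a few shape adapters) with hand-written
backward passes.  Every layer is gradient-checked against finite
differences in the test suite.

Conventions
-----------
* Dense inputs are ``[batch, features]``; a 3-D input ``[batch, time,
  features]`` is treated time-distributed (the dense map is applied to
  every time step).
* Conv1D / LSTM inputs are ``[batch, time, channels]``.
* Conv2D inputs are ``[batch, height, width, channels]``.
* ``forward(x, training)`` caches what ``backward(grad)`` needs;
  ``backward`` returns the gradient w.r.t. the layer input and stores
  parameter gradients in ``self.grads`` (same order as ``self.params``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Activation",
    "Conv1D",
    "Conv2D",
    "MaxPool1D",
    "MaxPool2D",
    "Upsample1D",
    "BatchNorm",
    "Dropout",
    "Flatten",
    "Reshape",
    "RepeatVector",
    "LSTM",
    "Bidirectional",
    "TimeDistributed",
    "MultiHead",
    "Sequential",
]


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: stateless by default, no parameters."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, activation=None):
        super().__init__()
        self.n_in, self.n_out = int(n_in), int(n_out)
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.act = Activation(activation) if activation else None

    def forward(self, x, training=False):
        self._shape = x.shape
        self._x2d = x.reshape(-1, self.n_in)
        y = self._x2d @ self.W + self.b
        y = y.reshape(*self._shape[:-1], self.n_out)
        if self.act is not None:
            y = self.act.forward(y, training)
        return y

    def backward(self, grad):
        if self.act is not None:
            grad = self.act.backward(grad)
        g2d = grad.reshape(-1, self.n_out)
        self.grads[0] += self._x2d.T @ g2d
        self.grads[1] += g2d.sum(axis=0)
        return (g2d @ self.W.T).reshape(self._shape)


class Activation(Layer):
    """Elementwise nonlinearity: relu, tanh, sigmoid or linear."""

    def __init__(self, kind):
        super().__init__()
        if kind not in ("relu", "tanh", "sigmoid", "linear", None):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind or "linear"

    def forward(self, x, training=False):
        if self.kind == "relu":
            self._mask = x > 0
            return np.where(self._mask, x, 0.0)
        if self.kind == "tanh":
            self._y = np.tanh(x)
            return self._y
        if self.kind == "sigmoid":
            self._y = _sigmoid(x)
            return self._y
        return x

    def backward(self, grad):
        if self.kind == "relu":
            return grad * self._mask
        if self.kind == "tanh":
            return grad * (1.0 - self._y**2)
        if self.kind == "sigmoid":
            return grad * self._y * (1.0 - self._y)
        return grad


class Conv1D(Layer):
    """1-D convolution over time, channels-last, via im2col."""

    def __init__(self, n_in, n_filters, kernel, rng, stride=1, padding="same",
                 activation=None):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        self.n_in, self.n_f, self.k = int(n_in), int(n_filters), int(kernel)
        self.stride, self.padding = int(stride), padding
        fan_in, fan_out = self.k * self.n_in, self.k * self.n_f
        self.W = _glorot(rng, (self.k * self.n_in, self.n_f), fan_in, fan_out)
        self.b = np.zeros(self.n_f)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.act = Activation(activation) if activation else None

    def _geometry(self, T):
        if self.padding == "same":
            T_out = -(-T // self.stride)
            pad = max((T_out - 1) * self.stride + self.k - T, 0)
        else:
            if T < self.k:
                raise ValueError(f"input length {T} shorter than kernel {self.k}")
            T_out = (T - self.k) // self.stride + 1
            pad = 0
        return T_out, pad // 2, pad - pad // 2

    def forward(self, x, training=False):
        B, T, C = x.shape
        T_out, p0, p1 = self._geometry(T)
        xp = np.pad(x, ((0, 0), (p0, p1), (0, 0))) if (p0 or p1) else x
        starts = np.arange(T_out) * self.stride
        idx = starts[:, None] + np.arange(self.k)[None, :]  # [T_out, k]
        col = xp[:, idx, :].reshape(B, T_out, self.k * C)
        self._cache = (col, x.shape, (T_out, p0, p1), idx)
        y = col @ self.W + self.b
        if self.act is not None:
            y = self.act.forward(y, training)
        return y

    def backward(self, grad):
        if self.act is not None:
            grad = self.act.backward(grad)
        col, xshape, (T_out, p0, p1), idx = self._cache
        B, T, C = xshape
        g2d = grad.reshape(-1, self.n_f)
        self.grads[0] += col.reshape(-1, self.k * C).T @ g2d
        self.grads[1] += g2d.sum(axis=0)
        dcol = (grad @ self.W.T).reshape(B, T_out, self.k, C)
        dxp = np.zeros((B, T + p0 + p1, C))
        np.add.at(dxp, (slice(None), idx, slice(None)), dcol)
        return dxp[:, p0:p0 + T, :]


class Conv2D(Layer):
    """2-D convolution, channels-last, via im2col."""

    def __init__(self, n_in, n_filters, kernel, rng, padding="same",
                 activation=None):
        super().__init__()
        self.n_in, self.n_f = int(n_in), int(n_filters)
        self.kh, self.kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        self.padding = padding
        fan_in = self.kh * self.kw * self.n_in
        fan_out = self.kh * self.kw * self.n_f
        self.W = _glorot(rng, (fan_in, self.n_f), fan_in, fan_out)
        self.b = np.zeros(self.n_f)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.act = Activation(activation) if activation else None

    def forward(self, x, training=False):
        B, H, Wd, C = x.shape
        if self.padding == "same":
            ph, pw = self.kh - 1, self.kw - 1
            ph0, pw0 = ph // 2, pw // 2
            H_out, W_out = H, Wd
        else:
            ph = pw = ph0 = pw0 = 0
            H_out, W_out = H - self.kh + 1, Wd - self.kw + 1
        xp = np.pad(x, ((0, 0), (ph0, ph - ph0), (pw0, pw - pw0), (0, 0)))
        ih = (np.arange(H_out)[:, None] + np.arange(self.kh)[None, :])  # [H_out, kh]
        iw = (np.arange(W_out)[:, None] + np.arange(self.kw)[None, :])
        # gather to [B, H_out, kh, W_out, kw, C] then reorder
        patches = xp[:, ih][:, :, :, iw]  # [B,H_out,kh,W_out,kw,C]
        col = patches.transpose(0, 1, 3, 2, 4, 5).reshape(
            B, H_out, W_out, self.kh * self.kw * C)
        self._cache = (col, x.shape, xp.shape, (ih, iw, ph0, pw0))
        y = col @ self.W + self.b
        if self.act is not None:
            y = self.act.forward(y, training)
        return y

    def backward(self, grad):
        if self.act is not None:
            grad = self.act.backward(grad)
        col, xshape, xpshape, (ih, iw, ph0, pw0) = self._cache
        B, H, Wd, C = xshape
        H_out, W_out = grad.shape[1], grad.shape[2]
        g2d = grad.reshape(-1, self.n_f)
        self.grads[0] += col.reshape(-1, col.shape[-1]).T @ g2d
        self.grads[1] += g2d.sum(axis=0)
        dcol = (grad @ self.W.T).reshape(B, H_out, W_out, self.kh, self.kw, C)
        dpatches = dcol.transpose(0, 1, 3, 2, 4, 5)  # [B,H_out,kh,W_out,kw,C]
        dxp = np.zeros(xpshape)
        np.add.at(dxp, (slice(None), ih[:, :, None, None],
                        iw[None, None, :, :]), dpatches)
        return dxp[:, ph0:ph0 + H, pw0:pw0 + Wd, :]


class MaxPool1D(Layer):
    """Non-overlapping max pooling over time; trailing remainder cropped."""

    def __init__(self, pool=2):
        super().__init__()
        self.pool = int(pool)

    def forward(self, x, training=False):
        B, T, C = x.shape
        T_out = T // self.pool
        xr = x[:, :T_out * self.pool, :].reshape(B, T_out, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad):
        B, T, C = self._shape
        T_out = T // self.pool
        dxr = np.zeros((B, T_out, self.pool, C))
        bi, ti, ci = np.ogrid[:B, :T_out, :C]
        dxr[bi, ti, self._argmax, ci] = grad
        dx = np.zeros((B, T, C))
        dx[:, :T_out * self.pool, :] = dxr.reshape(B, T_out * self.pool, C)
        return dx


class MaxPool2D(Layer):
    def __init__(self, pool=(2, 2)):
        super().__init__()
        self.ph, self.pw = (pool, pool) if np.isscalar(pool) else pool

    def forward(self, x, training=False):
        B, H, Wd, C = x.shape
        Ho, Wo = H // self.ph, Wd // self.pw
        xr = x[:, :Ho * self.ph, :Wo * self.pw, :].reshape(
            B, Ho, self.ph, Wo, self.pw, C)
        xr = xr.transpose(0, 1, 3, 2, 4, 5).reshape(B, Ho, Wo, self.ph * self.pw, C)
        self._argmax = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, grad):
        B, H, Wd, C = self._shape
        Ho, Wo = H // self.ph, Wd // self.pw
        dxr = np.zeros((B, Ho, Wo, self.ph * self.pw, C))
        bi, hi, wi, ci = np.ogrid[:B, :Ho, :Wo, :C]
        dxr[bi, hi, wi, self._argmax, ci] = grad
        dxr = dxr.reshape(B, Ho, Wo, self.ph, self.pw, C).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros((B, H, Wd, C))
        dx[:, :Ho * self.ph, :Wo * self.pw, :] = dxr.reshape(
            B, Ho * self.ph, Wo * self.pw, C)
        return dx


class Upsample1D(Layer):
    """Nearest-neighbour repeat along time (decoder counterpart of pooling)."""

    def __init__(self, factor=2):
        super().__init__()
        self.factor = int(factor)

    def forward(self, x, training=False):
        self._T = x.shape[1]
        return np.repeat(x, self.factor, axis=1)

    def backward(self, grad):
        B, _, C = grad.shape
        return grad.reshape(B, self._T, self.factor, C).sum(axis=2)


class BatchNorm(Layer):
    """Batch normalization over all axes except the last (features)."""

    def __init__(self, n_features, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum, self.eps = momentum, eps
        self._seen_batch = False

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if not self._seen_batch:
                # seed the EMA with the first batch so short trainings
                # don't carry the arbitrary (0, 1) initialization
                self.running_mean = mean.copy()
                self.running_var = var.copy()
                self._seen_batch = True
            else:
                self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
                self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv
        self._axes = axes
        self._m = x.size // x.shape[-1]
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = self._axes
        self.grads[0] += (grad * self._xhat).sum(axis=axes)
        self.grads[1] += grad.sum(axis=axes)
        if not self._training:
            return grad * self.gamma * self._inv
        m = self._m
        gx = grad * self.gamma
        return (self._inv / m) * (
            m * gx - gx.sum(axis=axes) - self._xhat * (gx * self._xhat).sum(axis=axes))


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    """Reshape per sample (batch axis preserved)."""

    def __init__(self, shape):
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x, training=False):
        self._in = x.shape
        return x.reshape(x.shape[0], *self.shape)

    def backward(self, grad):
        return grad.reshape(self._in)


class RepeatVector(Layer):
    """[B, D] -> [B, n, D]."""

    def __init__(self, n):
        super().__init__()
        self.n = int(n)

    def forward(self, x, training=False):
        return np.repeat(x[:, None, :], self.n, axis=1)

    def backward(self, grad):
        return grad.sum(axis=1)


class LSTM(Layer):
    """Single-direction LSTM with fused backprop-through-time.

    Gate order i, f, g, o; forget-gate bias initialized to 1.
    """

    def __init__(self, n_in, n_hidden, rng, return_sequences=False):
        super().__init__()
        self.n_in, self.H = int(n_in), int(n_hidden)
        H = self.H
        self.Wx = _glorot(rng, (n_in, 4 * H), n_in, 4 * H)
        self.Wh = _glorot(rng, (H, 4 * H), H, 4 * H)
        self.b = np.zeros(4 * H)
        self.b[H:2 * H] = 1.0
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.return_sequences = return_sequences

    def forward(self, x, training=False):
        B, T, _ = x.shape
        H = self.H
        xW = x.reshape(B * T, -1) @ self.Wx
        xW = xW.reshape(B, T, 4 * H)
        hs = np.zeros((T + 1, B, H))
        cs = np.zeros((T + 1, B, H))
        gates = np.empty((T, B, 4 * H))
        tanh_c = np.empty((T, B, H))
        for t in range(T):
            a = xW[:, t] + hs[t] @ self.Wh + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            cs[t + 1] = f * cs[t] + i * g
            tanh_c[t] = np.tanh(cs[t + 1])
            hs[t + 1] = o * tanh_c[t]
            gates[t] = np.concatenate([i, f, g, o], axis=1)
        self._cache = (x, hs, cs, gates, tanh_c)
        if self.return_sequences:
            return hs[1:].transpose(1, 0, 2)
        return hs[-1]

    def backward(self, grad):
        x, hs, cs, gates, tanh_c = self._cache
        B, T, _ = x.shape
        H = self.H
        if self.return_sequences:
            gseq = grad.transpose(1, 0, 2)  # [T, B, H]
        else:
            gseq = None
        dh = np.zeros((B, H)) if gseq is not None else grad.copy()
        dc = np.zeros((B, H))
        dx = np.empty_like(x)
        dWx, dWh, db = self.grads
        for t in range(T - 1, -1, -1):
            if gseq is not None:
                dh = dh + gseq[t]
            i, f, g, o = (gates[t][:, :H], gates[t][:, H:2 * H],
                          gates[t][:, 2 * H:3 * H], gates[t][:, 3 * H:])
            do = dh * tanh_c[t]
            dc = dc + dh * o * (1.0 - tanh_c[t] ** 2)
            di, df, dg = dc * g, dc * cs[t], dc * i
            da = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g**2), do * o * (1 - o)], axis=1)
            dWx += x[:, t].T @ da
            dWh += hs[t].T @ da
            db += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.T
            dh = da @ self.Wh.T
            dc = dc * f
        return dx


class Bidirectional(Layer):
    """Runs a forward and a time-reversed LSTM; concatenates features."""

    def __init__(self, n_in, n_hidden, rng, return_sequences=False):
        super().__init__()
        self.fwd = LSTM(n_in, n_hidden, rng, return_sequences)
        self.bwd = LSTM(n_in, n_hidden, rng, return_sequences)
        self.return_sequences = return_sequences
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x, training=False):
        yf = self.fwd.forward(x, training)
        yb = self.bwd.forward(x[:, ::-1, :], training)
        if self.return_sequences:
            yb = yb[:, ::-1, :]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, grad):
        H = self.fwd.H
        gf, gb = grad[..., :H], grad[..., H:]
        if self.return_sequences:
            gb = gb[:, ::-1, :]
        dxf = self.fwd.backward(np.ascontiguousarray(gf))
        dxb = self.bwd.backward(np.ascontiguousarray(gb))
        return dxf + dxb[:, ::-1, :]


class TimeDistributed(Layer):
    """Applies an inner layer independently to each time slice.

    Input [B, S, ...] is folded to [B*S, ...] for the inner layer.
    """

    def __init__(self, inner):
        super().__init__()
        self.inner = inner
        self.params = inner.params
        self.grads = inner.grads

    def forward(self, x, training=False):
        B, S = x.shape[:2]
        self._BS = (B, S)
        y = self.inner.forward(x.reshape(B * S, *x.shape[2:]), training)
        return y.reshape(B, S, *y.shape[1:])

    def backward(self, grad):
        B, S = self._BS
        dx = self.inner.backward(grad.reshape(B * S, *grad.shape[2:]))
        return dx.reshape(B, S, *dx.shape[1:])


class MultiHead(Layer):
    """Parallel branches over the same input, concatenated on the last axis."""

    def __init__(self, branches):
        super().__init__()
        self.branches = list(branches)
        self.params = [p for b in self.branches for p in b.params]
        self.grads = [g for b in self.branches for g in b.grads]

    def forward(self, x, training=False):
        ys = [b.forward(x, training) for b in self.branches]
        self._widths = [y.shape[-1] for y in ys]
        return np.concatenate(ys, axis=-1)

    def backward(self, grad):
        dx = None
        ofs = 0
        for b, w in zip(self.branches, self._widths):
            g = np.ascontiguousarray(grad[..., ofs:ofs + w])
            d = b.backward(g)
            dx = d if dx is None else dx + d
            ofs += w
        return dx


class Sequential(Layer):
    def __init__(self, layers=()):
        super().__init__()
        self.layers = list(layers)
        self._collect()

    def _collect(self):
        self.params = [p for l in self.layers for p in l.params]
        self.grads = [g for l in self.layers for g in l.grads]

    def add(self, layer):
        self.layers.append(layer)
        self._collect()

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()
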