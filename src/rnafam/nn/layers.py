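"""Layers with explicit forward/backward passes.

Every layer follows the same contract: ``build(in_shape, rng)`` allocates
parameters given the per-sample input shape (batch axis excluded, time axis
may be ``None`` for recurrent inputs) and returns the output shape;
``forward(x, mode, rng, mask)`` computes activations and caches what the
matching ``backward(dout)`` needs. ``mode`` is one of:

* ``"train"`` — dropout and Gaussian noise active, batch-norm uses batch
  statistics and updates its running averages;
* ``"eval"`` — fully deterministic;
* ``"mc"``   — Monte Carlo Dropout inference: dropout active, batch norm
  and Gaussian noise in their deterministic inference behaviour.

``mask`` is a boolean (n, T) validity mask used only by recurrent layers;
non-recurrent layers pass it through untouched.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def build(self, in_shape, rng):
        return in_shape

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x, mode="eval", rng=None, mask=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, units: int):
        self.units = units

    def build(self, in_shape, rng):
        (d,) = in_shape
        self.W = Parameter(rng.normal(0.0, np.sqrt(2.0 / d), size=(d, self.units)))
        self.b = Parameter(np.zeros(self.units))
        return (self.units,)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, mode="eval", rng=None, mask=None):
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dout):
        # a dense layer runs once per pass, so the gradient can be written
        # in place instead of accumulated (saves a large temporary)
        np.matmul(self._x.T, dout, out=self.W.grad)
        np.sum(dout, axis=0, out=self.b.grad)
        return dout @ self.W.data.T


class Conv1D(Layer):
    """Same-padded 1D convolution over (L, C) inputs, stride 1."""

    def __init__(self, filters: int, kernel: int = 3):
        self.filters = filters
        self.kernel = kernel

    def build(self, in_shape, rng):
        L, C = in_shape
        fan_in = self.kernel * C
        self.W = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, self.filters)))
        self.b = Parameter(np.zeros(self.filters))
        self._C = C
        return (L, self.filters)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, mode="eval", rng=None, mask=None):
        n, L, C = x.shape
        p = (self.kernel - 1) // 2
        xp = np.pad(x, ((0, 0), (p, self.kernel - 1 - p), (0, 0)))
        cols = sliding_window_view(xp, self.kernel, axis=1)  # (n, L, C, k)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(n, L, self.kernel * C)
        self._cols = cols
        self._in_shape = x.shape
        return cols @ self.W.data + self.b.data

    def backward(self, dout):
        n, L, C = self._in_shape
        k = self.kernel
        p = (k - 1) // 2
        cols2d = self._cols.reshape(n * L, k * C)
        np.matmul(cols2d.T, dout.reshape(n * L, self.filters), out=self.W.grad)
        self.b.grad[...] = dout.sum(axis=(0, 1))
        dcols = (dout @ self.W.data.T).reshape(n, L, k, C)
        dxp = np.zeros((n, L + k - 1, C), dtype=dout.dtype)
        for j in range(k):
            dxp[:, j : j + L, :] += dcols[:, :, j, :]
        return dxp[:, p : p + L, :]


class Conv2D(Layer):
    """Same-padded 2D convolution over (H, W, C) inputs, stride 1."""

    def __init__(self, filters: int, kernel: int = 3):
        self.filters = filters
        self.kernel = kernel

    def build(self, in_shape, rng):
        H, W, C = in_shape
        fan_in = self.kernel * self.kernel * C
        self.K = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(self.kernel, self.kernel, C, self.filters))
        )
        self.b = Parameter(np.zeros(self.filters))
        return (H, W, self.filters)

    def params(self):
        return [self.K, self.b]

    def forward(self, x, mode="eval", rng=None, mask=None):
        n, H, W, C = x.shape
        k = self.kernel
        p = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (p, k - 1 - p), (p, k - 1 - p), (0, 0)))
        # im2col: one (n*H*W, k*k*C) block and a single GEMM
        cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # (n, H, W, C, k, k)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
        self._cols = cols.reshape(n * H * W, k * k * C)
        self._in_shape = x.shape
        W2 = self.K.data.reshape(k * k * C, self.filters)
        y = self._cols @ W2
        return y.reshape(n, H, W, self.filters) + self.b.data

    def backward(self, dout):
        n, H, W, C = self._in_shape
        k = self.kernel
        p = (k - 1) // 2
        flat = dout.reshape(n * H * W, self.filters)
        np.matmul(self._cols.T, flat, out=self.K.grad.reshape(k * k * C, self.filters))
        self.b.grad[...] = flat.sum(axis=0)
        W2 = self.K.data.reshape(k * k * C, self.filters)
        dcols = (flat @ W2.T).reshape(n, H, W, k, k, C)
        dxp = np.zeros((n, H + k - 1, W + k - 1, C), dtype=dout.dtype)
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + H, dj : dj + W, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, p : p + H, p : p + W, :]


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing odd position is dropped.

    Degenerates to identity when the length is below the pool size, so deep
    stacks remain buildable on short inputs.
    """

    def __init__(self, pool: int = 2):
        self.pool = pool

    def build(self, in_shape, rng):
        L, C = in_shape
        if L < self.pool:
            return (L, C)
        return (L // self.pool, C)

    def forward(self, x, mode="eval", rng=None, mask=None):
        n, L, C = x.shape
        if L < self.pool:
            self._identity = True
            return x
        self._identity = False
        self._in_shape = x.shape
        L2 = L // self.pool
        if self.pool == 2:
            # branch-free pairwise max; ties resolve to the earlier position
            a = x[:, 0 : 2 * L2 : 2, :]
            b = x[:, 1 : 2 * L2 : 2, :]
            self._first = a >= b
            return np.where(self._first, a, b)
        xr = x[:, : L2 * self.pool].reshape(n, L2, self.pool, C)
        self._idx = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2).squeeze(2)

    def backward(self, dout):
        if self._identity:
            return dout
        n, L, C = self._in_shape
        L2 = L // self.pool
        dx = np.zeros((n, L, C), dtype=dout.dtype)
        if self.pool == 2:
            dx[:, 0 : 2 * L2 : 2, :] = np.where(self._first, dout, 0.0)
            dx[:, 1 : 2 * L2 : 2, :] = np.where(self._first, 0.0, dout)
            return dx
        dxr = np.zeros((n, L2, self.pool, C), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[:, :, None, :], dout[:, :, None, :], axis=2)
        dx[:, : L2 * self.pool] = dxr.reshape(n, L2 * self.pool, C)
        return dx


class MaxPool2D(Layer):
    """Non-overlapping 2D max pooling; trailing odd rows/columns dropped;
    identity along an axis already shorter than the pool size."""

    def __init__(self, pool: int = 2):
        if pool != 2:
            raise ValueError("MaxPool2D supports a pool size of 2")
        self.pool = pool

    def _factors(self, H, W):
        return (self.pool if H >= self.pool else 1, self.pool if W >= self.pool else 1)

    def build(self, in_shape, rng):
        H, W, C = in_shape
        ph, pw = self._factors(H, W)
        return (H // ph, W // pw, C)

    def forward(self, x, mode="eval", rng=None, mask=None):
        n, H, W, C = x.shape
        ph, pw = self._factors(H, W)
        H2, W2 = H // ph, W // pw
        self._meta = (x.shape, ph, pw)
        # pairwise max along W then H; ties resolve to the earlier cell
        if pw == 2:
            a = x[:, :, 0 : 2 * W2 : 2, :]
            b = x[:, :, 1 : 2 * W2 : 2, :]
            self._first_w = a >= b
            y = np.where(self._first_w, a, b)
        else:
            y = x[:, :, : W2 * pw, :]
        if ph == 2:
            a = y[:, 0 : 2 * H2 : 2, :, :]
            b = y[:, 1 : 2 * H2 : 2, :, :]
            self._first_h = a >= b
            y = np.where(self._first_h, a, b)
        else:
            y = y[:, : H2 * ph, :, :]
        return y

    def backward(self, dout):
        (n, H, W, C), ph, pw = self._meta
        H2, W2 = H // ph, W // pw
        if ph == 2:
            dh = np.zeros((n, H, W2, C), dtype=dout.dtype)
            dh[:, 0 : 2 * H2 : 2] = np.where(self._first_h, dout, 0.0)
            dh[:, 1 : 2 * H2 : 2] = np.where(self._first_h, 0.0, dout)
        else:
            dh = np.zeros((n, H, W2, C), dtype=dout.dtype)
            dh[:, : H2 * ph] = dout
        dx = np.zeros((n, H, W, C), dtype=dout.dtype)
        if pw == 2:
            dx[:, :, 0 : 2 * W2 : 2] = np.where(self._first_w, dh, 0.0)
            dx[:, :, 1 : 2 * W2 : 2] = np.where(self._first_w, 0.0, dh)
        else:
            dx[:, :, : W2 * pw] = dh
        return dx


class ReLU(Layer):
    def forward(self, x, mode="eval", rng=None, mask=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x, mode="eval", rng=None, mask=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Flatten(Layer):
    def build(self, in_shape, rng):
        return (int(np.prod(in_shape)),)

    def forward(self, x, mode="eval", rng=None, mask=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; active in 'train' and 'mc' modes.

    The inverted convention divides retained activations by the keep
    probability, so the expected activation is preserved and no rescaling
    is needed at deterministic inference.
    """

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, mode="eval", rng=None, mask=None):
        if mode in ("train", "mc") and self.rate > 0.0:
            keep = 1.0 - self.rate
            self._mask = (rng.random(x.shape, dtype=np.float32) < keep).astype(x.dtype)
            self._mask /= keep
            return x * self._mask
        self._mask = None
        return x

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class GaussianNoise(Layer):
    """Additive Gaussian noise regularization; active only in 'train'."""

    def __init__(self, std: float = 0.1):
        self.std = std

    def forward(self, x, mode="eval", rng=None, mask=None):
        if mode == "train" and self.std > 0.0:
            return x + rng.normal(0.0, self.std, size=x.shape).astype(x.dtype)
        return x

    def backward(self, dout):
        return dout


class BatchNorm(Layer):
    """Batch normalization over all axes but the trailing channel axis."""

    def __init__(self, momentum: float = 0.9, eps: float = 1e-5):
        self.momentum = momentum
        self.eps = eps

    def build(self, in_shape, rng):
        C = in_shape[-1]
        self.gamma = Parameter(np.ones(C))
        self.beta = Parameter(np.zeros(C))
        self.running_mean = np.zeros(C, dtype=np.float32)
        self.running_var = np.ones(C, dtype=np.float32)
        return in_shape

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, mode="eval", rng=None, mask=None):
        axes = tuple(range(x.ndim - 1))
        if mode == "train":
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean = self.running_mean
            var = self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivstd
        self._cache = (xhat, ivstd, axes, mode, x.shape)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dout):
        xhat, ivstd, axes, mode, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.data
        if mode != "train":
            return dxhat * ivstd
        m = np.prod([shape[a] for a in axes])
        return (
            ivstd
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        )


class LSTM(Layer):
    """Single-direction LSTM over (n, T, d) with a boolean validity mask.

    At masked (padding) timesteps the hidden and cell states are carried
    forward unchanged, so the final state is the state at each sample's
    true length. ``return_sequences`` controls whether the full hidden
    sequence (n, T, units) or the final state (n, units) is emitted.
    """

    def __init__(self, units: int, return_sequences: bool = False):
        self.units = units
        self.return_sequences = return_sequences

    def build(self, in_shape, rng):
        T, d = in_shape
        u = self.units
        s = np.sqrt(1.0 / max(d, 1))
        self.W = Parameter(rng.uniform(-s, s, size=(d, 4 * u)))
        self.U = Parameter(rng.uniform(-s, s, size=(u, 4 * u)))
        b = np.zeros(4 * u, dtype=np.float32)
        b[u : 2 * u] = 1.0  # forget-gate bias
        self.b = Parameter(b)
        if self.return_sequences:
            return (T, u)
        return (u,)

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, x, mode="eval", rng=None, mask=None):
        n, T, d = x.shape
        u = self.units
        if mask is None:
            mask = np.ones((n, T), dtype=bool)
        h = np.zeros((n, u), dtype=x.dtype)
        c = np.zeros((n, u), dtype=x.dtype)
        self._cache = []
        hs = np.zeros((n, T, u), dtype=x.dtype)
        for t in range(T):
            m = mask[:, t : t + 1].astype(x.dtype)
            z = x[:, t, :] @ self.W.data + h @ self.U.data + self.b.data
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((x[:, t, :], h, c, i, f, g, o, c_new, tc, m))
            c = m * c_new + (1 - m) * c
            h = m * h_new + (1 - m) * h
            hs[:, t, :] = h
        self._T, self._n, self._d = T, n, d
        return hs if self.return_sequences else h

    def backward(self, dout):
        n, T, d, u = self._n, self._T, self._d, self.units
        dh_carry = np.zeros((n, u), dtype=np.float32)
        dc_carry = np.zeros((n, u), dtype=np.float32)
        dx = np.zeros((n, T, d), dtype=np.float32)
        if not self.return_sequences:
            dh_carry = dout.astype(np.float32)
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tc, m = self._cache[t]
            dh_total = dh_carry + (dout[:, t, :] if self.return_sequences else 0.0)
            dh_new = dh_total * m
            dh_prev = dh_total * (1 - m)
            dc_new = dc_carry * m
            dc_prev = dc_carry * (1 - m)
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1 - tc * tc)
            df = dc_new * c_prev
            dc_prev = dc_prev + dc_new * f
            di = dc_new * g
            dg = dc_new * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            self.W.grad += x_t.T @ da
            self.U.grad += h_prev.T @ da
            self.b.grad += da.sum(axis=0)
            dx[:, t, :] = da @ self.W.data.T
            dh_carry = dh_prev + da @ self.U.data.T
            dc_carry = dc_prev
        return dx


def _reverse_valid(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sample along the time axis within its valid prefix."""
    out = x.copy()
    for idx, L in enumerate(lengths):
        L = int(L)
        if L > 1:
            out[idx, :L] = x[idx, :L][::-1]
    return out


class Bidirectional(Layer):
    """Bidirectional wrapper concatenating forward and time-reversed LSTMs."""

    def __init__(self, units: int, return_sequences: bool = False):
        self.units = units
        self.return_sequences = return_sequences
        self.fwd = LSTM(units, return_sequences=return_sequences)
        self.bwd = LSTM(units, return_sequences=return_sequences)

    def build(self, in_shape, rng):
        out_f = self.fwd.build(in_shape, rng)
        self.bwd.build(in_shape, rng)
        if self.return_sequences:
            return (out_f[0], 2 * self.units)
        return (2 * self.units,)

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x, mode="eval", rng=None, mask=None):
        n, T, _ = x.shape
        if mask is None:
            mask = np.ones((n, T), dtype=bool)
        self._lengths = mask.sum(axis=1)
        y_f = self.fwd.forward(x, mode, rng, mask)
        y_b = self.bwd.forward(_reverse_valid(x, self._lengths), mode, rng, mask)
        if self.return_sequences:
            y_b = _reverse_valid(y_b, self._lengths)
        return np.concatenate([y_f, y_b], axis=-1)

    def backward(self, dout):
        u = self.units
        d_f, d_b = dout[..., :u], dout[..., u:]
        if self.return_sequences:
            d_b = _reverse_valid(np.ascontiguousarray(d_b), self._lengths)
        dx_f = self.fwd.backward(np.ascontiguousarray(d_f))
        dx_b = _reverse_valid(self.bwd.backward(d_b), self._lengths)
        return dx_f + dx_b


class Sequential:
    """An ordered stack of layers with shape inference and (de)serialization."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)
        self.built = False

    def build(self, input_shape: tuple, rng: np.random.Generator) -> "Sequential":
        shape = tuple(input_shape)
        for layer in self.layers:
            shape = layer.build(shape, rng)
        self.output_shape = shape
        self.built = True
        return self

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def has_dropout(self) -> bool:
        return any(isinstance(l, Dropout) and l.rate > 0 for l in self.layers)

    def forward(self, x, mode="eval", rng=None, mask=None):
        consumed = False
        for layer in self.layers:
            x = layer.forward(x, mode=mode, rng=rng, mask=None if consumed else mask)
            if isinstance(layer, (LSTM, Bidirectional)) and not layer.return_sequences:
                consumed = True
            if isinstance(layer, Flatten):
                consumed = True
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                arrays.append(layer.running_mean.copy())
                arrays.append(layer.running_var.copy())
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        for p, a in zip(params, arrays[: len(params)]):
            p.data = np.asarray(a, dtype=np.float32).copy()
        extra = iter(arrays[len(params) :])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(next(extra), dtype=np.float32).copy()
                layer.running_var = np.asarray(next(extra), dtype=np.float32).copy()
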