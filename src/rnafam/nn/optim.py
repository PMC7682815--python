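"""Adam / AMSGrad optimization.

The update is written with in-place numpy operations and per-parameter
scratch buffers: on large dense layers the optimizer is memory-bandwidth
bound, and avoiding temporaries roughly halves its cost.
"""

from __future__ import annotations

import numpy as np

from .layers import Parameter

try:  # single-pass fused update; the pure-numpy path remains equivalent
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _fused_adam(p, g, m, v, b1, b2, step_size, inv_sqrt_bias2, eps):
        for i in range(p.size):
            gi = g[i]
            mi = b1 * m[i] + (1.0 - b1) * gi
            vi = b2 * v[i] + (1.0 - b2) * gi * gi
            m[i] = mi
            v[i] = vi
            p[i] -= step_size * mi / (np.sqrt(vi) * inv_sqrt_bias2 + eps)

except ImportError:  # pragma: no cover - numba is a standard dependency
    _fused_adam = None


class Adam:
    """Adam with optional AMSGrad second-moment maximum."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        amsgrad: bool = False,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.amsgrad = amsgrad
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.vhat = [np.zeros_like(p.data) for p in params] if amsgrad else None
        self._scratch = [np.empty_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        # p -= lr/bias1 * m / (sqrt(v/bias2) + eps), all in place
        step_size = np.float32(self.lr / bias1)
        inv_sqrt_bias2 = np.float32(1.0 / np.sqrt(bias2))
        eps = np.float32(self.eps)
        one_minus_b1 = np.float32(1.0 - b1)
        one_minus_b2 = np.float32(1.0 - b2)
        for i, p in enumerate(self.params):
            g = p.grad
            m, v, s = self.m[i], self.v[i], self._scratch[i]
            if _fused_adam is not None and not self.amsgrad and p.data.size > 4096:
                _fused_adam(
                    p.data.ravel(), g.ravel(), m.ravel(), v.ravel(),
                    np.float32(b1), np.float32(b2), step_size,
                    inv_sqrt_bias2, eps,
                )
                continue
            m *= np.float32(b1)
            np.multiply(g, one_minus_b1, out=s)
            m += s
            v *= np.float32(b2)
            np.multiply(g, g, out=s)
            s *= one_minus_b2
            v += s
            if self.amsgrad:
                np.maximum(self.vhat[i], v, out=self.vhat[i])
                v = self.vhat[i]
            np.sqrt(v, out=s)
            s *= inv_sqrt_bias2
            s += eps
            np.divide(m, s, out=s)
            s *= step_size
            p.data -= s
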