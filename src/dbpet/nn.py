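"""Minimal CPU neural-network core used by the residual denoiser.

Implements exactly the pieces the denoiser architecture needs — 2D same-size
convolution, batch normalization, channel-wise PReLU, mean-squared-error loss
and the Adam optimizer — as numpy layers with hand-written backpropagation.
Tensors are ``(batch, channels, rows, cols)`` float32; convolution is
computed in the Fourier domain (rfft2 + channel einsum), which for the large
kernels used here is much cheaper than explicit patch extraction.

Every layer exposes ``forward(x, training)`` and ``backward(dy)`` (returning
dx and accumulating parameter gradients), and lists its parameters as
:class:`Parameter` objects consumed by :class:`Adam`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Parameter", "Conv2d", "BatchNorm2d", "PReLU", "Sequential", "Adam",
           "mse_loss"]

_DTYPE = np.float32


class Parameter:
    """A trainable tensor with its gradient accumulator."""

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Conv2d:
    """Same-size (zero-padded) 2D cross-correlation with odd square kernels.

    Computed in the Fourier domain: the padded input, the kernels and the
    upstream gradient are FFT'd once per pass and combined with channel
    einsums, which is far cheaper than explicit patch extraction for the
    large kernels this architecture uses.  Weights are stored as
    ``(c_out, c_in * k * k)``.

    ``init="he"`` draws weights from the seeded He-normal distribution;
    ``init="zeros"`` makes the layer (and any residual head built on it)
    start as the zero map.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, init: str = "he"):
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError("kernel size must be a positive odd integer")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        if init == "he":
            w = rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        elif init == "zeros":
            w = np.zeros((c_out, fan_in))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out))
        self._x_shape = None
        self._xpf = None

    @property
    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def _fft_shape(self, h: int, w: int) -> tuple[int, int]:
        from scipy.fft import next_fast_len

        p2 = 2 * (self.kernel // 2)
        return next_fast_len(h + p2), next_fast_len(w + p2)

    def _kernel_fft(self, s: tuple[int, int]) -> np.ndarray:
        from scipy.fft import rfft2

        k = self.kernel
        w_full = self.weight.value.reshape(self.c_out, self.c_in, k, k)
        return rfft2(w_full, s=s)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        from scipy.fft import irfft2, rfft2

        b, c, h, w = x.shape
        p = self.kernel // 2
        s = self._fft_shape(h, w)
        xp = np.pad(x.astype(_DTYPE), ((0, 0), (0, 0), (p, p), (p, p)))
        xpf = rfft2(xp, s=s)
        wf = self._kernel_fft(s)
        # y[i] = sum_u w[u] * xpad[i+u]  ==  cross-correlation at lags 0..H-1
        yf = np.einsum("bcxy,ocxy->boxy", xpf, np.conj(wf), optimize=True)
        y = irfft2(yf, s=s)[..., :h, :w]
        if training:
            self._x_shape = x.shape
            self._xpf = xpf
        return (y + self.bias.value[:, None, None]).astype(_DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        from scipy.fft import irfft2, rfft2

        b, c, h, w = self._x_shape
        k, p = self.kernel, self.kernel // 2
        s = self._fft_shape(h, w)
        dy = dy.astype(_DTYPE)
        dyf = rfft2(dy, s=s)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        # dW[o,c,u] = sum_{b,i} dy[b,o,i] * xpad[b,c,i+u]: lags 0..2p
        dwf = np.einsum("bcxy,boxy->ocxy", self._xpf, np.conj(dyf), optimize=True)
        dw = irfft2(dwf, s=s)[..., :k, :k]
        self.weight.grad += dw.reshape(self.c_out, -1).astype(_DTYPE)
        # dx[t] = sum_u w[u] * dy[t+p-u]: linear convolution, offset p
        wf = self._kernel_fft(s)
        dxf = np.einsum("boxy,ocxy->bcxy", dyf, wf, optimize=True)
        dx = irfft2(dxf, s=s)[..., p:p + h, p:p + w]
        self._xpf = None
        return dx.astype(_DTYPE)


class BatchNorm2d:
    """Per-channel batch normalization over (batch, rows, cols).

    Training uses batch statistics and updates exponential running estimates
    (momentum 0.1); inference normalizes with the stored running statistics.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)
        self._cache = None

    @property
    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(_DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if training:
            self._cache = (xhat, inv)
        return (self.gamma.value[:, None, None] * xhat
                + self.beta.value[:, None, None])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3)).astype(_DTYPE)
        self.beta.grad += dy.sum(axis=(0, 2, 3)).astype(_DTYPE)
        g = self.gamma.value[:, None, None]
        dxhat = dy * g
        dx = (inv[:, None, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 2, 3))[:, None, None]
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        )
        self._cache = None
        return dx.astype(_DTYPE)


class PReLU:
    """Channel-wise parametric ReLU: y = max(0,x) + a_c * min(0,x)."""

    def __init__(self, c: int, init_slope: float = 0.25):
        self.alpha = Parameter(np.full(c, init_slope))
        self._x = None

    @property
    def parameters(self) -> list[Parameter]:
        return [self.alpha]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        a = self.alpha.value[:, None, None]
        return np.where(x >= 0, x, a * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        neg = x < 0
        self.alpha.grad += np.where(neg, dy * x, 0).sum(axis=(0, 2, 3)).astype(_DTYPE)
        a = self.alpha.value[:, None, None]
        dx = np.where(neg, dy * a, dy)
        self._x = None
        return dx.astype(_DTYPE)


class Sequential:
    def __init__(self, layers: list):
        self.layers = list(layers)

    @property
    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad[...] = 0


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = (pred - target).astype(_DTYPE)
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad


class Adam:
    """Adam optimizer with the standard defaults (b1 0.9, b2 0.999, eps 1e-8)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
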