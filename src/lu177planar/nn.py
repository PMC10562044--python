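"""Minimal convolutional-network engine on numpy.

Implements exactly what the densely-connected denoiser needs: stride-1
"same" 2D convolutions (im2col + GEMM, channels-last layout), ReLU,
channel concatenation handled by the network graph, He/MSRA
variance-scaled initialization, an RMSE loss and an Adam optimizer with
L2 weight decay.  Gradients are hand-derived and verified against finite
differences in the test suite.

Arrays are ``(N, H, W, C)`` float32 by default; float64 is supported for
gradient checking.
"""

from __future__ import annotations

import numpy as np


class _Workspace:
    """Reusable unfold buffers, keyed by input shape.

    Repeated minibatch iterations hit the same shapes; reusing the padded
    and column buffers avoids large fresh allocations (and their page
    faults) every convolution call.  The padded buffer's zero border is
    written once and persists because only the interior is overwritten.
    """

    def __init__(self) -> None:
        self.shape: tuple | None = None
        self.xp: np.ndarray | None = None
        self.cols: np.ndarray | None = None

    def unfold(self, x: np.ndarray, k: int) -> np.ndarray:
        """(n, h, w, c) -> tap-major (k*k, n*h*w, c); plane t = ki*k+kj
        holds the input shifted by the kernel offset (ki, kj)."""
        n, h, w, c = x.shape
        p = k // 2
        key = (x.shape, k, x.dtype)
        if self.shape != key:
            self.xp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=x.dtype)
            self.cols = np.empty((k * k, n, h, w, c), dtype=x.dtype)
            self.shape = key
        xp, cols = self.xp, self.cols
        xp[:, p:p + h, p:p + w, :] = x
        t = 0
        for i in range(k):
            for j in range(k):
                cols[t] = xp[:, i:i + h, j:j + w, :]
                t += 1
        return cols.reshape(k * k, n * h * w, c)

    def unfold_rows(self, x: np.ndarray, k: int) -> np.ndarray:
        """(n, h, w, c) -> row-major (n*h*w, k*k*c) unfold.

        Suited to few-channel inputs (the output-gradient side of the
        convolution backward), where the strided destination writes are
        cheap and the single fat-K GEMM they enable avoids nine
        accumulation passes over the full-size input gradient.
        """
        n, h, w, c = x.shape
        p = k // 2
        key = (x.shape, k, x.dtype, "rows")
        if self.shape != key:
            self.xp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=x.dtype)
            self.cols = np.empty((n, h, w, k * k, c), dtype=x.dtype)
            self.shape = key
        xp, cols = self.xp, self.cols
        xp[:, p:p + h, p:p + w, :] = x
        t = 0
        for i in range(k):
            for j in range(k):
                cols[:, :, :, t, :] = xp[:, i:i + h, j:j + w, :]
                t += 1
        return cols.reshape(n * h * w, k * k * c)


class Conv2d:
    """Stride-1 same-padding 2D convolution.

    Weights are ``(k*k*c_in, c_out)``, He-initialized
    (``std = sqrt(2 / fan_in)``), biases zero.  A stride-1 transposed
    convolution is mathematically a plain convolution with a flipped
    kernel; since kernels are learned, the two are interchangeable and
    this class serves for both.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        if c_in < 1 or c_out < 1 or kernel < 1 or kernel % 2 == 0:
            raise ValueError("channels >= 1 and odd kernel required")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = kernel * kernel * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (fan_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None
        self._ws = _Workspace()
        self._dws = _Workspace()

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        k = self.k
        if k == 1:
            cols = x.reshape(1, n * h * w, c)
        else:
            cols = self._ws.unfold(x, k)
        wt = self.W.reshape(k * k, c, self.c_out)
        y = cols[0] @ wt[0]
        for t in range(1, k * k):
            y += cols[t] @ wt[t]
        y += self.b
        if cache:
            self._cols, self._in_shape = cols, (n, h, w, c)
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray, need_dx: bool = True
                 ) -> np.ndarray | None:
        if self._cols is None:
            raise RuntimeError("backward before forward")
        n, h, w, c = self._in_shape
        k, kk = self.k, self.k * self.k
        dym = np.ascontiguousarray(dy).reshape(n * h * w, self.c_out)
        dwt = self.dW.reshape(kk, c, self.c_out)
        for t in range(kk):
            np.matmul(self._cols[t].T, dym, out=dwt[t])
        self.db = dym.sum(axis=0)
        if not need_dx:
            return None
        if k == 1:
            return (dym @ self.W.T).reshape(n, h, w, c)
        # input gradient of a same conv = same conv of dy with the
        # spatially flipped, channel-transposed kernel, as one fat-K GEMM
        wt = self.W.reshape(kk, c, self.c_out)
        w_flip = np.ascontiguousarray(
            wt[::-1].transpose(0, 2, 1)).reshape(kk * self.c_out, c)
        dyrows = self._dws.unfold_rows(dym.reshape(n, h, w, self.c_out), k)
        return (dyrows @ w_flip).reshape(n, h, w, c)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    @property
    def n_weights(self) -> int:
        return self.W.size + self.b.size


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0, out=x)


def relu_grad(dy: np.ndarray, activated: np.ndarray) -> np.ndarray:
    return np.where(activated > 0, dy, 0.0)


def rmse_loss(pred: np.ndarray, target: np.ndarray
              ) -> tuple[float, np.ndarray]:
    """Root-mean-square error and its gradient with respect to ``pred``."""
    r = (pred - target).astype(np.float64)
    loss = float(np.sqrt(np.mean(r * r)))
    if loss == 0.0:
        return 0.0, np.zeros_like(pred)
    grad = (r / (loss * r.size)).astype(pred.dtype)
    return loss, grad


class Adam:
    """Adam with decoupled weight decay on the convolution weights.

    ``beta1`` is the momentum term of the configuration; ``beta2`` and
    ``eps`` use the customary defaults.  The decay is applied directly to
    the parameters (AdamW form) rather than folded into the gradient:
    coupling L2 into Adam's adaptive step divides the penalty by the
    gradient scale, which for a near-converged RMSE loss amplifies it by
    orders of magnitude and shrinks the network's output intensities by
    a few percent.  Biases are never decayed.
    """

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = params
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.eps, self.wd = eps, weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.wd and p.ndim > 1:  # decay weights, never biases
                p -= self.lr * self.wd * p
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
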