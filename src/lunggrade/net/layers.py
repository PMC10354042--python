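"""Minimal NumPy building blocks for the fully-convolutional grader.

Convolutions are im2col + matmul with explicit backward passes; the
transposed convolution is restricted to kernel == stride (exact tiling
upsample), which keeps both directions a pure reshape.  Everything runs in
float32 on one CPU and is deterministic under a seeded Generator.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _pair_indices(size: int, k: int, stride: int, dilation: int, pad: int):
    eff = dilation * (k - 1) + 1
    out = (size + 2 * pad - eff) // stride + 1
    if out < 1:
        raise ValueError("kernel larger than padded input")
    base = dilation * np.arange(k)
    starts = stride * np.arange(out)
    return base, starts, out


def im2col(x: np.ndarray, k: int, stride: int, dilation: int, pad: int):
    """(N,C,H,W) -> (N, C*k*k, OH*OW) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    bi, si, oh = _pair_indices(h, k, stride, dilation, pad)
    bj, sj, ow = _pair_indices(w, k, stride, dilation, pad)
    rows = bi[:, None] + si[None, :]  # (k, OH)
    colsx = bj[:, None] + sj[None, :]  # (k, OW)
    # (N, C, k, OH, k, OW) -> (N, C, k, k, OH, OW)
    patches = x[:, :, rows[:, :, None, None], colsx[None, None, :, :]]
    patches = patches.transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(patches.reshape(n, c * k * k, oh * ow)), (oh, ow)


def col2im(cols: np.ndarray, x_shape, k: int, stride: int, dilation: int, pad: int):
    """Adjoint of :func:`im2col` (scatter-add back into the input frame)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    bi, si, oh = _pair_indices(h, k, stride, dilation, pad)
    bj, sj, ow = _pair_indices(w, k, stride, dilation, pad)
    rows = (bi[:, None] + si[None, :])[:, :, None, None]  # (k, OH, 1, 1)
    colsx = (bj[:, None] + sj[None, :])[None, None, :, :]  # (1, 1, k, OW)
    patches = cols.reshape(n, c, k, k, oh, ow).transpose(0, 1, 2, 4, 3, 5)
    np.add.at(out, (slice(None), slice(None), rows, colsx), patches)
    return out[:, :, pad : pad + h, pad : pad + w] if pad else out


class Conv2d:
    """Same-padded 2-D convolution with optional stride and dilation."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 1,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.W = Param(w)
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.dilation = k, stride, dilation
        self.pad = dilation * (k - 1) // 2
        self.cin, self.cout = cin, cout
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (oh, ow) = im2col(x, self.k, self.stride, self.dilation, self.pad)
        y = self.W.value @ cols + self.b.value[:, None]
        self._cache = (cols, x.shape)
        n = x.shape[0]
        return y.reshape(n, self.cout, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, -1)
        self.W.grad += np.einsum("nop,ncp->oc", dyf, cols).reshape(self.W.value.shape)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.einsum("oc,nop->ncp", self.W.value, dyf)
        return col2im(dcols, x_shape, self.k, self.stride, self.dilation, self.pad)


class ConvTranspose2d:
    """Exact-tiling transposed convolution (kernel == stride).

    Upsamples (N,C,h,w) to (N,C',h*s,w*s); each output sxs tile is a linear
    map of one input pixel, so forward and backward are reshapes.
    """

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.s = stride
        self.cin, self.cout = cin, cout
        w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout * stride * stride))
        self.W = Param(w)
        self.b = Param(np.zeros(cout))
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.s
        xf = x.reshape(n, c, h * w)
        y = np.einsum("ck,ncp->nkp", self.W.value, xf)  # k = cout*s*s
        y = y.reshape(n, self.cout, s, s, h, w).transpose(0, 1, 4, 2, 5, 3)
        y = y.reshape(n, self.cout, h * s, w * s) + self.b.value[None, :, None, None]
        self._cache = (xf, (n, c, h, w))
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf, (n, c, h, w) = self._cache
        s = self.s
        d = dy.reshape(n, self.cout, h, s, w, s).transpose(0, 1, 3, 5, 2, 4)
        d = d.reshape(n, self.cout * s * s, h * w)
        self.W.grad += np.einsum("nkp,ncp->ck", d, xf)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("ck,nkp->ncp", self.W.value, d)
        return dx.reshape(n, c, h, w)


class ReLU:
    params: list = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class PreActResidualBlock:
    """Pre-activation residual block: x + conv(relu(conv(relu(x))))."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.r1, self.r2 = ReLU(), ReLU()
        self.c1 = Conv2d(channels, channels, 3, rng=rng)
        self.c2 = Conv2d(channels, channels, 3, rng=rng)

    @property
    def params(self):
        return self.c1.params + self.c2.params

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.c2.forward(self.r2.forward(self.c1.forward(self.r1.forward(x))))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.r1.backward(self.c1.backward(self.r2.backward(self.c2.backward(dy))))
        return dy + d


class Adam:
    """Adaptive moment estimation over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p.value -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the channel axis of (N,C,H,W)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(
    logits: np.ndarray, targets: np.ndarray, ignore_mask: np.ndarray | None = None
):
    """Mean pixelwise cross-entropy; returns (loss, dlogits).

    ``targets`` holds class indices (N,H,W); pixels where ``ignore_mask``
    is True contribute nothing.
    """
    probs = softmax_channels(logits)
    n, c, h, w = logits.shape
    valid = np.ones((n, h, w), dtype=bool) if ignore_mask is None else ~ignore_mask
    count = max(int(valid.sum()), 1)
    idx_n, idx_h, idx_w = np.nonzero(valid)
    t = targets[idx_n, idx_h, idx_w]
    picked = probs[idx_n, t, idx_h, idx_w]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean()) if len(t) else 0.0
    dlogits = probs.copy()
    dlogits[idx_n, t, idx_h, idx_w] -= 1.0
    dlogits *= valid[:, None, :, :] / count
    return loss, dlogits.astype(np.float32)
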