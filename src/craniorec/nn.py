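"""Minimal volumetric neural-network primitives (NumPy, CPU).

Implements exactly the pieces the reconstruction and enhancement networks
need -- 3-D convolution (im2col + BLAS matmul), batch normalisation, ReLU,
2x max-pooling, 2x transposed convolution, sigmoid -- each with an explicit
``backward`` so the whole stack is differentiable without an autograd
framework.  Everything is float32 and fully deterministic for a fixed
``numpy.random.Generator``.

Layers follow a common micro-protocol: ``forward(x, training)`` caches what
``backward(grad)`` needs; ``params()`` returns trainable :class:`Param`
objects in a stable order and ``buffers()`` the non-trainable state
(batch-norm running moments).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Sigmoid",
    "MaxPool3d",
    "ConvTranspose3d",
    "ResBlock",
    "Adam",
    "trilinear_upsample2",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        return []

    def freeze(self):
        for p in self.params():
            p.trainable = False

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params() if p.trainable)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, X, Y, Z) -> (N * XYZ, C * k^3) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    n, c, ox, oy, oz = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    return np.ascontiguousarray(cols).reshape(n * ox * oy * oz, c * k**3), (n, ox, oy, oz)


def _corr3d(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Cross-correlate (N,C,...) with w (Cout, Cin, k, k, k)."""
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    cols, (n, ox, oy, oz) = _im2col(x, k, pad)
    out = cols @ w.reshape(cout, cin * k**3).T
    return out.reshape(n, ox, oy, oz, cout).transpose(0, 4, 1, 2, 3)


class Conv3d(Layer):
    """k^3 convolution, stride 1, 'same' padding for odd k (He init)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        std = np.sqrt(2.0 / (cin * k**3))
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, k, k, k)))
        self.b = Param(np.zeros(cout))
        self._cols = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        x = np.asarray(x)
        cols, (n, ox, oy, oz) = _im2col(x, self.k, self.pad)
        out = cols @ self.W.value.reshape(self.cout, -1).T + self.b.value
        self._cols = cols if training else None
        return out.reshape(n, ox, oy, oz, self.cout).transpose(0, 4, 1, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dm = np.ascontiguousarray(dout.transpose(0, 2, 3, 4, 1)).reshape(-1, self.cout)
        self.W.grad += (dm.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += dm.sum(axis=0)
        self._cols = None
        w_flip = self.W.value.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        return _corr3d(dout, np.ascontiguousarray(w_flip), pad=self.k - 1 - self.pad)

    def params(self):
        return [self.W, self.b]


class BatchNorm3d(Layer):
    """Per-channel batch normalisation over (N, X, Y, Z)."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        x = np.asarray(x)
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * ivar.reshape(shape)
        if training:
            self._cache = (xhat, ivar)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        m = dout.size // dout.shape[1]
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(shape)
        term = (
            m * dxhat
            - dxhat.sum(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape)
        )
        return (ivar.reshape(shape) / m) * term

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]


class ReLU(Layer):
    def forward(self, x, training: bool = True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Sigmoid(Layer):
    def forward(self, x, training: bool = True):
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        self._out = out
        return out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2 (dims must be even)."""

    def forward(self, x, training: bool = True):
        n, c, X, Y, Z = x.shape
        r = x.reshape(n, c, X // 2, 2, Y // 2, 2, Z // 2, 2)
        r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, X // 2, Y // 2, Z // 2, 8
        )
        self._argmax = r.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(r, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, X, Y, Z = self._shape
        d = np.zeros((n, c, X // 2, Y // 2, Z // 2, 8), dtype=dout.dtype)
        np.put_along_axis(d, self._argmax[..., None], dout[..., None], axis=-1)
        d = d.reshape(n, c, X // 2, Y // 2, Z // 2, 2, 2, 2)
        return d.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, X, Y, Z)


class ConvTranspose3d(Layer):
    """2x upsampling transposed convolution, kernel 2, stride 2."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / (cin * 8))
        self.W = Param(rng.normal(0.0, std, size=(cin, cout, 2, 2, 2)))
        self.b = Param(np.zeros(cout))

    def forward(self, x, training: bool = True):
        x = np.asarray(x)
        self._x = x if training else None
        n, c, X, Y, Z = x.shape
        out = np.einsum("ncxyz,cdijk->ndxiyjzk", x, self.W.value, optimize=True)
        out = out.reshape(n, self.cout, 2 * X, 2 * Y, 2 * Z)
        return out + self.b.value.reshape(1, -1, 1, 1, 1)

    def backward(self, dout):
        n, d, X2, Y2, Z2 = dout.shape
        dr = dout.reshape(n, d, X2 // 2, 2, Y2 // 2, 2, Z2 // 2, 2)
        dr = dr.transpose(0, 1, 2, 4, 6, 3, 5, 7)  # n d x y z i j k
        self.W.grad += np.einsum(
            "ncxyz,ndxyzijk->cdijk", self._x, dr, optimize=True
        )
        self.b.grad += dout.sum(axis=(0, 2, 3, 4))
        dx = np.einsum("ndxyzijk,cdijk->ncxyz", dr, self.W.value, optimize=True)
        self._x = None
        return dx

    def params(self):
        return [self.W, self.b]


class ResBlock(Layer):
    """conv-BN-ReLU-conv-BN plus identity (or 1^3-projection) shortcut."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv3d(cin, cout, 3, rng)
        self.bn1 = BatchNorm3d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(cout, cout, 3, rng)
        self.bn2 = BatchNorm3d(cout)
        if cin != cout:
            self.proj = Conv3d(cin, cout, 1, rng)
            self.bnp = BatchNorm3d(cout)
        else:
            self.proj = self.bnp = None
        self.relu_out = ReLU()

    def forward(self, x, training: bool = True):
        h = self.conv1.forward(x, training)
        h = self.relu1.forward(self.bn1.forward(h, training))
        h = self.bn2.forward(self.conv2.forward(h, training), training)
        if self.proj is not None:
            s = self.bnp.forward(self.proj.forward(x, training), training)
        else:
            s = x
        return self.relu_out.forward(h + s)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dh = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(d))))
        )
        if self.proj is not None:
            ds = self.proj.backward(self.bnp.backward(d))
        else:
            ds = d
        return dh + ds

    def _children(self):
        out = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            out += [self.proj, self.bnp]
        return out

    def params(self):
        return [p for c in self._children() for p in c.params()]

    def buffers(self):
        return [b for c in self._children() for b in c.buffers()]


def trilinear_upsample2(x: np.ndarray) -> np.ndarray:
    """Trilinear 2x upsampling of an (N, C, X, Y, Z) array (no gradient:
    used only on constant input pathways)."""
    from scipy import ndimage

    n, c = x.shape[:2]
    out = np.empty((n, c) + tuple(2 * s for s in x.shape[2:]), dtype=np.float32)
    for i in range(n):
        for j in range(c):
            out[i, j] = ndimage.zoom(
                x[i, j].astype(np.float32), 2, order=1, grid_mode=True,
                mode="nearest",
            )
    return out


class Adam:
    """Adam optimizer over a parameter list (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
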