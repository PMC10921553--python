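"""Minimal 3D convolutional network engine (numpy + numba).

Implements exactly the pieces the residual U-Net needs — 3x3x3 convolution,
1x1x1 convolution, instance normalisation, ReLU/sigmoid, 2x max-pooling,
2x trilinear upsampling and Adam — with hand-written backward passes.
Tensors are laid out ``(C, N, X, Y, Z)`` in float32; the channel-major layout
keeps the convolution GEMM/kernels contiguous.

The 3x3x3 convolution kernels are register-blocked numba loops (a direct
convolution avoids the im2col memory traffic that dominates on one core).
The backward pass w.r.t. the input reuses the forward kernel with spatially
flipped, channel-transposed weights; the weight gradient has its own kernel.
"""
from __future__ import annotations

import numpy as np
import numba

__all__ = [
    "Param",
    "Conv3",
    "Conv1",
    "InstanceNorm",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "TrilinearUp2",
    "ResidualBlock",
    "Adam",
]

F32 = np.float32


@numba.njit(cache=True, fastmath=True)
def _conv3_fwd(xp, w, out):  # pragma: no cover - exercised via Conv3
    """out[o,n] = sum_c xp[c,n] * w[o,c]; xp is pre-padded by 1 voxel."""
    O, C = w.shape[0], w.shape[1]
    N, X, Y, Z = out.shape[1], out.shape[2], out.shape[3], out.shape[4]
    for n in range(N):
        for o0 in range(0, O, 4):
            ob = O - o0
            for x in range(X):
                for y in range(Y):
                    a0 = np.zeros(Z, dtype=np.float32)
                    a1 = np.zeros(Z, dtype=np.float32)
                    a2 = np.zeros(Z, dtype=np.float32)
                    a3 = np.zeros(Z, dtype=np.float32)
                    for c in range(C):
                        for dx in range(3):
                            for dy in range(3):
                                row = xp[c, n, x + dx, y + dy]
                                for dz in range(3):
                                    w0 = w[o0, c, dx, dy, dz]
                                    w1 = w[o0 + 1, c, dx, dy, dz] if ob > 1 else F32(0)
                                    w2 = w[o0 + 2, c, dx, dy, dz] if ob > 2 else F32(0)
                                    w3 = w[o0 + 3, c, dx, dy, dz] if ob > 3 else F32(0)
                                    for z in range(Z):
                                        v = row[z + dz]
                                        a0[z] += w0 * v
                                        a1[z] += w1 * v
                                        a2[z] += w2 * v
                                        a3[z] += w3 * v
                    out[o0, n, x, y] = a0
                    if ob > 1:
                        out[o0 + 1, n, x, y] = a1
                    if ob > 2:
                        out[o0 + 2, n, x, y] = a2
                    if ob > 3:
                        out[o0 + 3, n, x, y] = a3


@numba.njit(cache=True, fastmath=True)
def _conv3_dw(xp, dout, dw):  # pragma: no cover - exercised via Conv3
    """dw[o,c,dx,dy,dz] = sum_{n,x,y,z} xp[c,n,x+dx,y+dy,z+dz] * dout[o,n,x,y,z].

    Single streaming pass: the (O, C, 27) accumulator block stays in cache
    while both tensors are read once.
    """
    O, C = dw.shape[0], dw.shape[1]
    N, X, Y, Z = dout.shape[1], dout.shape[2], dout.shape[3], dout.shape[4]
    dw[...] = 0.0
    for n in range(N):
        for x in range(X):
            for y in range(Y):
                for o in range(O):
                    rowd = dout[o, n, x, y]
                    for c in range(C):
                        for dx in range(3):
                            for dy in range(3):
                                rowx = xp[c, n, x + dx, y + dy]
                                s0 = 0.0
                                s1 = 0.0
                                s2 = 0.0
                                for z in range(Z):
                                    d = rowd[z]
                                    s0 += rowx[z] * d
                                    s1 += rowx[z + 1] * d
                                    s2 += rowx[z + 2] * d
                                dw[o, c, dx, dy, 0] += s0
                                dw[o, c, dx, dy, 1] += s1
                                dw[o, c, dx, dy, 2] += s2


def _pad1(x: np.ndarray) -> np.ndarray:
    C, N, X, Y, Z = x.shape
    out = np.zeros((C, N, X + 2, Y + 2, Z + 2), dtype=F32)
    out[:, :, 1:-1, 1:-1, 1:-1] = x
    return out


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


class Conv3:
    """3x3x3 same-padding convolution, stride 1, no bias (a norm follows)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * 27))
        self.w = Param(rng.normal(0.0, std, size=(cout, cin, 3, 3, 3)))
        self.cin, self.cout = cin, cout
        self._xp = None

    def params(self):
        return [self.w]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xp = _pad1(x)
        C, N, X, Y, Z = x.shape
        out = np.empty((self.cout, N, X, Y, Z), dtype=F32)
        _conv3_fwd(self._xp, self.w.value, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.ascontiguousarray(dout, dtype=F32)
        dw = np.empty_like(self.w.value, dtype=np.float64)
        _conv3_dw(self._xp, dout, dw)
        self.w.grad += dw.astype(F32)
        # dx: convolve dout with flipped kernels, channels transposed
        wt = np.ascontiguousarray(
            self.w.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        _, N, X, Y, Z = dout.shape
        dx = np.empty((self.cin, N, X, Y, Z), dtype=F32)
        _conv3_fwd(_pad1(dout), wt, dx)
        self._xp = None
        return dx


class Conv1:
    """1x1x1 convolution (channel mixing), optional bias."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, bias: bool = False):
        std = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, std, size=(cout, cin)))
        self.b = Param(np.zeros(cout)) if bias else None
        self.cin, self.cout = cin, cout
        self._x = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        shp = x.shape
        y = self.w.value @ x.reshape(shp[0], -1)
        if self.b is not None:
            y += self.b.value[:, None]
        return y.reshape((self.cout,) + shp[1:])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        shp = self._x.shape
        dflat = dout.reshape(self.cout, -1)
        xflat = self._x.reshape(shp[0], -1)
        self.w.grad += dflat @ xflat.T
        if self.b is not None:
            self.b.grad += dflat.sum(axis=1)
        dx = (self.w.value.T @ dflat).reshape(shp)
        self._x = None
        return dx


class InstanceNorm:
    """Per-sample, per-channel normalisation over the spatial axes."""

    EPS = 1e-5

    def __init__(self, c: int):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, N = x.shape[:2]
        flat = x.reshape(C, N, -1)
        mu = flat.mean(axis=-1)
        m2 = np.einsum("cnv,cnv->cn", flat, flat) / flat.shape[-1]
        inv = (1.0 / np.sqrt(np.maximum(m2 - mu * mu, 0.0) + self.EPS)).astype(F32)
        xhat = np.empty_like(x)
        xf = xhat.reshape(C, N, -1)
        np.subtract(flat, mu.astype(F32)[:, :, None], out=xf)
        xf *= inv[:, :, None]
        self._cache = (xhat, inv)
        y = np.empty_like(x)
        yf = y.reshape(C, N, -1)
        np.multiply(xf, self.gamma.value[:, None, None], out=yf)
        yf += self.beta.value[:, None, None]
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        C, N = dout.shape[:2]
        df = dout.reshape(C, N, -1)
        xf = xhat.reshape(C, N, -1)
        self.gamma.grad += np.einsum("cnv,cnv->c", df, xf)
        self.beta.grad += df.sum(axis=(1, 2))
        g = self.gamma.value[:, None, None, None, None]
        dxhat = dout * g.astype(F32)
        dxf = dxhat.reshape(C, N, -1)
        m = dxf.mean(axis=-1)
        mx = np.einsum("cnv,cnv->cn", dxf, xf) / xf.shape[-1]
        sh = (C, N, 1, 1, 1)
        dx = inv.reshape(sh) * (
            dxhat - m.astype(F32).reshape(sh) - xhat * mx.astype(F32).reshape(sh)
        )
        self._cache = None
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dout, F32(0))
        self._mask = None
        return dx


class Sigmoid:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._y * (1.0 - self._y)
        self._y = None
        return dx.astype(F32)


class MaxPool2:
    """Max pooling with per-axis factors (default 2x2x2), stride = factor.

    Anisotropic factors such as (2, 2, 1) keep slice-axis resolution on
    thick-slice volumes where lesions span only a few slices.
    """

    def __init__(self, factors: tuple[int, int, int] = (2, 2, 2)):
        self.factors = tuple(int(f) for f in factors)
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, N, X, Y, Z = x.shape
        fx, fy, fz = self.factors
        v = x.reshape(C, N, X // fx, fx, Y // fy, fy, Z // fz, fz)
        v = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 6, 3, 5, 7))
        v = v.reshape(C, N, X // fx, Y // fy, Z // fz, fx * fy * fz)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, shp = self._cache
        C, N, X, Y, Z = shp
        fx, fy, fz = self.factors
        dv = np.zeros((C, N, X // fx, Y // fy, Z // fz, fx * fy * fz), dtype=F32)
        np.put_along_axis(dv, idx[..., None], dout[..., None].astype(F32), axis=-1)
        dv = dv.reshape(C, N, X // fx, Y // fy, Z // fz, fx, fy, fz)
        dx = dv.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(shp)
        self._cache = None
        return np.ascontiguousarray(dx)


class TrilinearUp2:
    """Doubling upsample with half-voxel-aligned linear interpolation.

    Separable per axis: output sample 2i is 0.75*x[i] + 0.25*x[i-1] and
    2i+1 is 0.75*x[i] + 0.25*x[i+1] (edges clamped), which is exactly the
    half-voxel-aligned linear interpolation at t = (j+0.5)/2 - 0.5.  The
    backward pass is the transposed operator.  Axes with factor 1 pass
    through untouched (mirror of anisotropic pooling).
    """

    def __init__(self, factors: tuple[int, int, int] = (2, 2, 2)):
        self.factors = tuple(int(f) for f in factors)
        self._in_shape = None

    def params(self):
        return []

    @staticmethod
    def _sl(ndim: int, axis: int, s: slice) -> tuple:
        out = [slice(None)] * ndim
        out[axis] = s
        return tuple(out)

    @classmethod
    def _up_axis(cls, x: np.ndarray, axis: int) -> np.ndarray:
        n = x.shape[axis]
        sl = lambda s: cls._sl(x.ndim, axis, s)
        shape = list(x.shape)
        shape[axis] = 2 * n
        out = np.empty(shape, dtype=F32)
        left = np.concatenate([x[sl(slice(0, 1))], x[sl(slice(0, n - 1))]], axis=axis)
        right = np.concatenate([x[sl(slice(1, n))], x[sl(slice(n - 1, n))]], axis=axis)
        out[sl(slice(0, None, 2))] = F32(0.75) * x + F32(0.25) * left
        out[sl(slice(1, None, 2))] = F32(0.75) * x + F32(0.25) * right
        return out

    @classmethod
    def _down_axis(cls, d: np.ndarray, axis: int) -> np.ndarray:
        """Transpose of :meth:`_up_axis` (gradient accumulation)."""
        sl = lambda s: cls._sl(d.ndim, axis, s)
        ev = d[sl(slice(0, None, 2))]
        od = d[sl(slice(1, None, 2))]
        out = F32(0.75) * (ev + od)
        out[sl(slice(0, -1))] += F32(0.25) * ev[sl(slice(1, None))]  # out[2(i+1)] <- 0.25*x[i]
        out[sl(slice(1, None))] += F32(0.25) * od[sl(slice(0, -1))]  # out[2(i-1)+1] <- 0.25*x[i]
        out[sl(slice(0, 1))] += F32(0.25) * ev[sl(slice(0, 1))]      # clamped left edge
        out[sl(slice(-1, None))] += F32(0.25) * od[sl(slice(-1, None))]  # clamped right edge
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        for ax, f in zip((2, 3, 4), self.factors):
            if f == 2:
                x = self._up_axis(x, ax)
        return np.ascontiguousarray(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for ax, f in zip((2, 3, 4), self.factors):
            if f == 2:
                dout = self._down_axis(dout, ax)
        return np.ascontiguousarray(dout)


class NormActConv1:
    """1x1x1 convolution preceded by instance norm + ReLU (channel fusion)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.norm = InstanceNorm(cin)
        self.act = ReLU()
        self.conv = Conv1(cin, cout, rng)

    def params(self):
        return self.norm.params() + self.conv.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.conv.forward(self.act.forward(self.norm.forward(x)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.norm.backward(self.act.backward(self.conv.backward(dout)))


class ResidualBlock:
    """conv-norm-relu x2 with an identity skip (1x1x1-projected on width change)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv3(cin, cout, rng)
        self.n1 = InstanceNorm(cout)
        self.r1 = ReLU()
        self.conv2 = Conv3(cout, cout, rng)
        self.n2 = InstanceNorm(cout)
        self.proj = Conv1(cin, cout, rng) if cin != cout else None
        self.r_out = ReLU()

    def params(self):
        ps = self.conv1.params() + self.n1.params() + self.conv2.params() + self.n2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.r1.forward(self.n1.forward(self.conv1.forward(x)))
        h = self.n2.forward(self.conv2.forward(h))
        s = self.proj.forward(x) if self.proj is not None else x
        return self.r_out.forward(h + s)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.r_out.backward(dout)
        dh = self.conv2.backward(self.n2.backward(d))
        dx = self.conv1.backward(self.n1.backward(self.r1.backward(dh)))
        if self.proj is not None:
            dx = dx + self.proj.backward(d)
        else:
            dx = dx + d
        return dx


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
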