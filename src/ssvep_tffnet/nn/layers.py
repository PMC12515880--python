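"""Neural-network layers on top of the autograd engine.

Implements the building blocks of the dual-branch SSVEP network:
2-D convolution (im2col + GEMM), batch/layer normalisation, PReLU,
dropout, adaptive average pooling and linear layers, each optionally
wrapped in spectral normalisation (weights divided by their largest
singular value, estimated by power iteration).
"""

from __future__ import annotations

import warnings

import numpy as np

from .autograd import Parameter, Tensor

try:  # JIT-compiled gather/scatter kernels; NumPy fallback below
    import numba

    @numba.njit(cache=False, fastmath=True)
    def _col2im_jit(dcols, N, Ho, Wo, Cin, kh, kw, Hp, Wp, sh, sw):
        dxp = np.zeros((N, Cin, Hp, Wp), dtype=dcols.dtype)
        row = 0
        for n in range(N):
            for ho in range(Ho):
                for wo in range(Wo):
                    col = 0
                    for ci in range(Cin):
                        for i in range(kh):
                            for j in range(kw):
                                dxp[n, ci, ho * sh + i, wo * sw + j] += dcols[row, col]
                                col += 1
                    row += 1
        return dxp

    @numba.njit(cache=False, fastmath=True)
    def _im2col_jit(xp, N, Ho, Wo, Cin, kh, kw, sh, sw):
        cols = np.empty((N * Ho * Wo, Cin * kh * kw), dtype=xp.dtype)
        row = 0
        for n in range(N):
            for ho in range(Ho):
                for wo in range(Wo):
                    col = 0
                    for ci in range(Cin):
                        for i in range(kh):
                            for j in range(kw):
                                cols[row, col] = xp[n, ci, ho * sh + i, wo * sw + j]
                                col += 1
                    row += 1
        return cols

    @numba.njit(cache=False, fastmath=True)
    def _prelu_fwd_jit(x3, a):
        out = np.empty_like(x3)
        P, C, Q = x3.shape
        for p in range(P):
            for c in range(C):
                ac = a[c]
                for q in range(Q):
                    v = x3[p, c, q]
                    out[p, c, q] = v if v > 0 else ac * v
        return out

    @numba.njit(cache=False, fastmath=True)
    def _prelu_bwd_jit(x3, g3, a):
        dx = np.empty_like(x3)
        da = np.zeros_like(a)
        P, C, Q = x3.shape
        for p in range(P):
            for c in range(C):
                ac = a[c]
                acc = 0.0
                for q in range(Q):
                    v = x3[p, c, q]
                    gv = g3[p, c, q]
                    if v > 0:
                        dx[p, c, q] = gv
                    else:
                        dx[p, c, q] = ac * gv
                        acc += gv * v
                da[c] += acc
        return dx, da

    @numba.njit(cache=False, fastmath=True)
    def _bn_stats_jit(x):
        N, C, H, W = x.shape
        s = np.zeros(C, dtype=np.float64)
        ss = np.zeros(C, dtype=np.float64)
        for n in range(N):
            for c in range(C):
                for h in range(H):
                    for w in range(W):
                        v = x[n, c, h, w]
                        s[c] += v
                        ss[c] += v * v
        m = N * H * W
        mean = s / m
        var = ss / m - mean * mean
        return mean, np.maximum(var, 0.0)

    @numba.njit(cache=False, fastmath=True)
    def _bn_fwd_jit(x, mean, inv, gamma, beta):
        out = np.empty_like(x)
        N, C, H, W = x.shape
        for n in range(N):
            for c in range(C):
                sc = gamma[c] * inv[c]
                off = beta[c] - sc * mean[c]
                for h in range(H):
                    for w in range(W):
                        out[n, c, h, w] = sc * x[n, c, h, w] + off
        return out

    @numba.njit(cache=False, fastmath=True)
    def _bn_bwd_jit(x, g, mean, inv, gamma, training):
        N, C, H, W = x.shape
        dgamma = np.zeros(C, dtype=np.float64)
        dbeta = np.zeros(C, dtype=np.float64)
        for n in range(N):
            for c in range(C):
                for h in range(H):
                    for w in range(W):
                        gv = g[n, c, h, w]
                        xhat = (x[n, c, h, w] - mean[c]) * inv[c]
                        dgamma[c] += gv * xhat
                        dbeta[c] += gv
        dx = np.empty_like(x)
        m = N * H * W
        for n in range(N):
            for c in range(C):
                gi = gamma[c] * inv[c]
                if training:
                    t1 = dbeta[c] / m
                    t2 = dgamma[c] / m
                    for h in range(H):
                        for w in range(W):
                            xhat = (x[n, c, h, w] - mean[c]) * inv[c]
                            dx[n, c, h, w] = gi * (g[n, c, h, w] - t1 - xhat * t2)
                else:
                    for h in range(H):
                        for w in range(W):
                            dx[n, c, h, w] = gi * g[n, c, h, w]
        return dx, dgamma, dbeta

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "LayerNorm",
    "PReLU",
    "Dropout",
    "AdaptiveAvgPool1d",
    "conv2d",
    "prelu",
    "spectral_scale",
    "power_iteration_sigma",
]


# ----------------------------------------------------------------------
# functional ops
# ----------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None,
           stride: tuple[int, int], padding: tuple[int, int]) -> Tensor:
    """2-D cross-correlation of ``x`` (N,Cin,H,W) with ``w`` (Cout,Cin,kh,kw)."""
    sh, sw = stride
    ph, pw = padding
    N, Cin, H, W = x.data.shape
    Cout, _, kh, kw = w.data.shape
    xp = x.data
    if ph or pw:
        xp = np.pad(xp, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho = (xp.shape[2] - kh) // sh + 1
    Wo = (xp.shape[3] - kw) // sw + 1
    if _HAVE_NUMBA:
        cols = _im2col_jit(np.ascontiguousarray(xp), N, Ho, Wo, Cin, kh, kw, sh, sw)
    else:
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::sh, ::sw]                   # N,Cin,Ho,Wo,kh,kw
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(N * Ho * Wo, Cin * kh * kw)
    wmat = w.data.reshape(Cout, Cin * kh * kw)
    out_data = cols @ wmat.T
    if b is not None:
        out_data += b.data
    out_data = out_data.reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(out_data), parents=parents)

    def bwd(g):
        gcols = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, Cout)
        if w.requires_grad:
            w._accum((gcols.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gcols.sum(axis=0))
        if x.requires_grad:
            dcols_flat = gcols @ wmat
            if _HAVE_NUMBA:
                dxp = _col2im_jit(dcols_flat, N, Ho, Wo, Cin, kh, kw,
                                  H + 2 * ph, W + 2 * pw, sh, sw)
            else:
                dcols = dcols_flat.reshape(N, Ho, Wo, Cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                dxp = np.zeros((N, Cin, H + 2 * ph, W + 2 * pw), dtype=x.data.dtype)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += dcols[:, :, :, :, i, j]
            if ph or pw:
                dxp = dxp[:, :, ph:H + ph, pw:W + pw]
            x._accum(dxp)

    out._backward = bwd
    return out


def prelu(x: Tensor, alpha: Tensor, channel_axis: int = 1) -> Tensor:
    """Parametric ReLU with one learnable slope per channel.

    Implemented via a cached per-element slope mask (1 where x > 0,
    alpha elsewhere) so forward and backward are single multiplies.
    """
    C = alpha.data.shape[0]
    if _HAVE_NUMBA:
        xs = x.data.shape
        pre = int(np.prod(xs[:channel_axis], dtype=np.int64))
        post = int(np.prod(xs[channel_axis + 1:], dtype=np.int64))
        x3 = np.ascontiguousarray(x.data).reshape(pre, C, post)
        out = Tensor(_prelu_fwd_jit(x3, alpha.data).reshape(xs), parents=(x, alpha))

        def bwd(g):
            g3 = np.ascontiguousarray(g).reshape(pre, C, post)
            dx, da = _prelu_bwd_jit(x3, g3, alpha.data)
            if x.requires_grad:
                x._accum(dx.reshape(xs))
            if alpha.requires_grad:
                alpha._accum(da)

        out._backward = bwd
        return out

    shape = [1] * x.data.ndim
    shape[channel_axis] = C
    a = alpha.data.reshape(shape)
    pos = x.data > 0
    slope = np.where(pos, x.data.dtype.type(1), a)
    out = Tensor(x.data * slope, parents=(x, alpha))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * slope)
        if alpha.requires_grad:
            gx = g * x.data
            gx *= ~pos                # only the negative part drives the slope
            axes = tuple(i for i in range(x.data.ndim) if i != channel_axis)
            alpha._accum(gx.sum(axis=axes).astype(alpha.data.dtype))

    out._backward = bwd
    return out


def spectral_scale(w: Tensor, u: np.ndarray, v: np.ndarray) -> Tensor:
    """Return ``w / sigma`` where ``sigma = u^T W_2d v`` (u, v constants).

    Gradients flow through the normalisation:
    ``dL/dW = g/sigma - (sum(g*W)/sigma^2) * u v^T``.
    """
    w2d = w.data.reshape(w.data.shape[0], -1)
    sigma = float(u @ w2d @ v)
    out = Tensor(w.data / sigma, parents=(w,))

    def bwd(g):
        g2d = g.reshape(w2d.shape)
        coef = float((g2d * w2d).sum()) / sigma**2
        grad = g / sigma - coef * np.outer(u, v).reshape(w.data.shape)
        w._accum(grad.astype(w.data.dtype))

    out._backward = bwd
    return out


def power_iteration_sigma(w2d: np.ndarray, u: np.ndarray,
                          n_steps: int = 1, eps: float = 1e-12):
    """Run ``n_steps`` of power iteration; return (sigma, u, v)."""
    v = None
    for _ in range(n_steps):
        v = w2d.T @ u
        v = v / (np.linalg.norm(v) + eps)
        u = w2d @ v
        u = u / (np.linalg.norm(u) + eps)
    if v is None:
        v = w2d.T @ u
        v = v / (np.linalg.norm(v) + eps)
    sigma = float(u @ w2d @ v)
    return sigma, u, v


# ----------------------------------------------------------------------
# modules
# ----------------------------------------------------------------------

class Module:
    """Base class: parameter discovery and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        for m in self.modules():
            for val in vars(m).values():
                if isinstance(val, Parameter):
                    params.append(val)
        return params

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class _SpectralNormMixin:
    """Maintains the power-iteration state for a weight matrix.

    One iteration step is taken per training-mode forward pass; the
    estimate is frozen in evaluation mode, matching the established
    algorithm for 1-Lipschitz weight constraints.
    """

    def _init_sn(self, rng: np.random.Generator, enabled: bool):
        self.spectral_norm = enabled
        w2d = self.weight.data.reshape(self.weight.data.shape[0], -1)
        u = rng.standard_normal(w2d.shape[0])
        self._sn_u = u / np.linalg.norm(u)
        self._sn_v: np.ndarray | None = None

    def effective_weight(self) -> Tensor:
        if not self.spectral_norm:
            return self.weight
        w2d = self.weight.data.reshape(self.weight.data.shape[0], -1)
        if float(np.abs(w2d).max()) == 0.0:
            warnings.warn("spectral normalization skipped: all-zero weight")
            return self.weight
        if self.training or self._sn_v is None:
            _, self._sn_u, self._sn_v = power_iteration_sigma(w2d, self._sn_u, n_steps=1)
        return spectral_scale(self.weight, self._sn_u, self._sn_v)

    def converge_sigma(self, n_steps: int = 100) -> float:
        """Refine the power-iteration estimate; returns the estimated sigma."""
        w2d = self.weight.data.reshape(self.weight.data.shape[0], -1)
        sigma, self._sn_u, self._sn_v = power_iteration_sigma(w2d, self._sn_u, n_steps)
        return sigma


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    # variance scaling for PReLU(0.25) activations
    gain = np.sqrt(2.0 / (1.0 + 0.25**2))
    std = gain / np.sqrt(fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2d(Module, _SpectralNormMixin):
    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 stride: tuple[int, int] = (1, 1), padding: tuple[int, int] = (0, 0),
                 rng: np.random.Generator | None = None, spectral_norm: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng()
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))
        self.stride = stride
        self.padding = padding
        self._init_sn(rng, spectral_norm)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.effective_weight(), self.bias, self.stride, self.padding)


class Linear(Module, _SpectralNormMixin):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, spectral_norm: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (out_dim, in_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32))
        self._init_sn(rng, spectral_norm)

    def __call__(self, x: Tensor) -> Tensor:
        w = self.effective_weight()
        return x.matmul(w.transpose(1, 0)) + self.bias


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel with running stats."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n_ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(n_ch, dtype=np.float32))
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        if self.training:
            if _HAVE_NUMBA:
                mean64, var64 = _bn_stats_jit(np.ascontiguousarray(x.data))
                mean = mean64.astype(np.float32)
                var = var64.astype(np.float32)
            else:
                mean = x.data.mean(axis=axes)
                var = x.data.var(axis=axes)
            n = x.data.size / x.data.shape[1]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)

        if _HAVE_NUMBA:
            gamma, beta, training = self.gamma, self.beta, self.training
            xc = np.ascontiguousarray(x.data)
            out = Tensor(_bn_fwd_jit(xc, mean, inv, gamma.data, beta.data),
                         parents=(x, gamma, beta))

            def bwd_jit(g):
                dx, dgamma, dbeta = _bn_bwd_jit(
                    xc, np.ascontiguousarray(g), mean, inv, gamma.data, training)
                if gamma.requires_grad:
                    gamma._accum(dgamma)
                if beta.requires_grad:
                    beta._accum(dbeta)
                if x.requires_grad:
                    x._accum(dx)

            out._backward = bwd_jit
            return out

        xhat_data = (x.data - mean.reshape(shape)) * inv.reshape(shape)
        out = Tensor(
            (self.gamma.data.reshape(shape) * xhat_data + self.beta.data.reshape(shape)).astype(x.data.dtype),
            parents=(x, self.gamma, self.beta),
        )
        gamma, beta, training, eps = self.gamma, self.beta, self.training, self.eps

        def bwd(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat_data).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if x.requires_grad:
                gx = g * gamma.data.reshape(shape)
                if training:
                    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                    dxhat = gx
                    dx = (inv.reshape(shape) / m) * (
                        m * dxhat
                        - dxhat.sum(axis=axes, keepdims=True)
                        - xhat_data * (dxhat * xhat_data).sum(axis=axes, keepdims=True)
                    )
                else:
                    dx = gx * inv.reshape(shape)
                x._accum(dx.astype(x.data.dtype))

        out._backward = bwd
        return out


class LayerNorm(Module):
    """Layer normalisation over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mean = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean) * inv
        out = Tensor((self.gamma.data * xhat + self.beta.data).astype(x.data.dtype),
                     parents=(x, self.gamma, self.beta))
        gamma, beta = self.gamma, self.beta
        d = x.data.shape[-1]

        def bwd(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
            if beta.requires_grad:
                beta._accum(g.sum(axis=tuple(range(g.ndim - 1))))
            if x.requires_grad:
                dxhat = g * gamma.data
                dx = (inv / d) * (
                    d * dxhat
                    - dxhat.sum(axis=-1, keepdims=True)
                    - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
                )
                x._accum(dx.astype(x.data.dtype))

        out._backward = bwd
        return out


class PReLU(Module):
    def __init__(self, n_ch: int, init: float = 0.25, channel_axis: int = 1):
        super().__init__()
        self.alpha = Parameter(np.full(n_ch, init, dtype=np.float32))
        self.channel_axis = channel_axis

    def __call__(self, x: Tensor) -> Tensor:
        return prelu(x, self.alpha, self.channel_axis)


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p).astype(x.data.dtype) / (1.0 - self.p)
        out = Tensor(x.data * mask, parents=(x,))
        out._backward = lambda g: x._accum(g * mask)
        return out


class AdaptiveAvgPool1d(Module):
    """Average pooling of a (N, C, L) sequence to a fixed output width.

    Output bin ``i`` averages input positions ``[floor(i*L/out), ceil((i+1)*L/out))``;
    for L < out, bins repeat positions, so short windows are upsampled by
    duplication-and-average rather than rejected.
    """

    def __init__(self, out_size: int):
        super().__init__()
        self.out_size = out_size
        self._mats: dict[int, np.ndarray] = {}

    def _matrix(self, L: int) -> np.ndarray:
        if L not in self._mats:
            P = np.zeros((L, self.out_size), dtype=np.float32)
            for i in range(self.out_size):
                lo = int(np.floor(i * L / self.out_size))
                hi = int(np.ceil((i + 1) * L / self.out_size))
                P[lo:hi, i] = 1.0 / (hi - lo)
            self._mats[L] = P
        return self._mats[L]

    def __call__(self, x: Tensor) -> Tensor:
        P = self._matrix(x.data.shape[-1])
        out = Tensor(x.data @ P, parents=(x,))
        out._backward = lambda g: x._accum(g @ P.T)
        return out
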