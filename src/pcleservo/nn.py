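"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small models (a strided conv encoder, bidirectional
diagonal state-space layers, affine heads) on a CPU, so the engine favors
clarity and determinism over throughput: float64 everywhere, dense numpy
kernels, explicit backward closures per op.  Only the operations the models
need are provided.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "s4d_causal_conv",
    "layer_norm",
    "gelu",
    "Module",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "Adam",
    "gradcheck",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def flip(self, axis):
        return flip(self, axis)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- elementwise and reduction ops ------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a = as_tensor(a)
    if isinstance(b, (int, float)):
        c = float(b)

        def backward_scalar(g):
            a._accumulate(g * c)

        return _node(a.data * c, (a,), backward_scalar)
    b = as_tensor(b)

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _node(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(g / a.data)

    return _node(np.log(a.data), (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - out_data ** 2))

    return _node(out_data, (a,), backward)


def absolute(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(g * np.sign(a.data))

    return _node(np.abs(a.data), (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(a.data * mask, (a,), backward)


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(a) -> Tensor:
    """Gaussian error linear unit (tanh approximation), with exact backward."""
    a = as_tensor(a)
    x = a.data
    inner = _GELU_C * (x + 0.044715 * x ** 3)
    t = np.tanh(inner)
    out_data = 0.5 * x * (1.0 + t)

    def backward(g):
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * x ** 2)
        grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
        a._accumulate(g * grad)

    return _node(out_data, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _node(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# -- shape ops ---------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    orig = a.data.shape

    def backward(g):
        a._accumulate(g.reshape(orig))

    return _node(a.data.reshape(shape), (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _node(a.data.transpose(axes), (a,), backward)


def flip(a, axis: int) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(np.flip(g, axis=axis))

    return _node(np.flip(a.data, axis=axis), (a,), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    return _node(a.data[idx], (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _node(out_data, tuple(tensors), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _node(out_data, (a, b), backward)


# -- composite layers --------------------------------------------------------

def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then affine."""
    mu = tmean(x, axis=-1, keepdims=True)
    centered = x - mu
    var = tmean(power(centered, 2.0), axis=-1, keepdims=True)
    inv = power(add(var, eps), -0.5)
    return add(mul(mul(centered, inv), gain), bias)


# -- convolution -------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    from numpy.lib.stride_tricks import sliding_window_view

    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = v.shape[2], v.shape[3]
    cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), x: [B,C,H,W], w: [O,C,kh,kw]."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    bs, cin, h, wd = x.data.shape
    cout, _, kh, kw = w.data.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(cout, -1)
    out = cols @ wmat.T + b.data
    out_data = out.transpose(0, 2, 1).reshape(bs, cout, ho, wo)

    def backward(g):
        gy = g.reshape(bs, cout, ho * wo).transpose(0, 2, 1)  # [B, HoWo, O]
        gb = gy.sum(axis=(0, 1))
        gw = np.einsum("bpo,bpk->ok", gy, cols).reshape(w.data.shape)
        if x.requires_grad or x._parents:
            gcols = gy @ wmat  # [B, HoWo, C*kh*kw]
            gcols = gcols.reshape(bs, ho, wo, cin, kh, kw)
            gxp = np.zeros((bs, cin, h + 2 * pad, wd + 2 * pad))
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            gx = gxp[:, :, pad : pad + h, pad : pad + wd] if pad else gxp
            x._accumulate(gx)
        w._accumulate(gw)
        b._accumulate(gb)

    return _node(out_data, (x, w, b), backward)


# -- diagonal state-space causal convolution ---------------------------------

def s4d_causal_conv(
    u: Tensor,
    c_re: Tensor,
    c_im: Tensor,
    d: Tensor,
    basis: np.ndarray,
) -> Tensor:
    """Causal convolution of u with an S4D kernel assembled at run time.

    u:      [B, L, H] real input sequence
    c_re/c_im: [H, N] trainable output map (real and imaginary parts)
    d:      [H] skip connection
    basis:  [H, N, L] complex constant, basis[h, n, l] = Bbar[h,n] * Abar[h,n]**l
            (state dynamics are fixed; the kernel is linear in C)

    K[h, l] = 2 * Re( sum_n C[h, n] * basis[h, n, l] )
    y[b, l, h] = sum_{j<=l} K[h, j] * u[b, l-j, h] + d[h] * u[b, l, h]
    """
    u, c_re, c_im, d = as_tensor(u), as_tensor(c_re), as_tensor(c_im), as_tensor(d)
    B, L, H = u.data.shape
    cc = c_re.data + 1j * c_im.data
    K = 2.0 * np.einsum("hn,hnl->hl", cc, basis).real  # [H, L]

    y = d.data * u.data
    for j in range(L):
        y[:, j:, :] += K[:, j] * u.data[:, : L - j, :]

    def backward(g):
        gK = np.empty((H, L))
        gu = d.data * g
        for j in range(L):
            gK[:, j] = np.einsum("blh,blh->h", g[:, j:, :], u.data[:, : L - j, :])
            gu[:, : L - j, :] += g[:, j:, :] * K[:, j]
        gc = 2.0 * np.einsum("hl,hnl->hn", gK, basis)
        c_re._accumulate(gc.real)
        c_im._accumulate(-gc.imag)
        d._accumulate(np.einsum("blh,blh->h", g, u.data))
        u._accumulate(gu)

    return _node(y, (u, c_re, c_im, d), backward)


# -- modules -----------------------------------------------------------------


class Module:
    """Parameter container with recursive discovery, in the torch idiom."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out[key] = value.data
            elif isinstance(value, Module):
                out.update(value.state_arrays(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        out[f"{key}.{i}"] = item.data
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                value.data = np.array(arrays[key], dtype=np.float64)
            elif isinstance(value, Module):
                value.load_state_arrays(arrays, prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_arrays(arrays, prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor):
                        item.data = np.array(arrays[f"{key}.{i}"], dtype=np.float64)


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor):
        return [value] if value.requires_grad else []
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for item in value:
            out.extend(_collect(item))
        return out
    return []


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(n_in)
        self.w = Tensor(rng.uniform(-scale, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.w), self.b)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int, pad: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(cin * kernel * kernel)
        self.w = Tensor(rng.uniform(-scale, scale, size=(cout, cin, kernel, kernel)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.g, self.b)


class Adam:
    """Adam optimizer; the learning rate may be changed between steps."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def gradcheck(fn, tensors: list[Tensor], eps: float = 1e-6, atol: float = 1e-5) -> float:
    """Compare analytic and central-difference gradients; returns max abs error."""
    for t in tensors:
        t.grad = None
    out = fn()
    out.backward()
    analytic = [np.array(t.grad) for t in tensors]
    worst = 0.0
    for t, ga in zip(tensors, analytic):
        flat = t.data.reshape(-1)
        num = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(fn().data)
            flat[i] = orig - eps
            lo = float(fn().data)
            flat[i] = orig
            num[i] = (hi - lo) / (2 * eps)
        worst = max(worst, float(np.max(np.abs(num - ga.reshape(-1)))))
        if worst > atol:
            raise AssertionError(f"gradcheck failed: max deviation {worst}")
    return worst
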