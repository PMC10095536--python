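"""Compact reverse-mode automatic differentiation core on numpy.

Provides the tensor type, the differentiable operations needed by the
segmentation network (2-D convolution, max pooling, bilinear upsampling,
global/channel pooling, sigmoid/softmax gates, label gathering for the
losses), a tiny ``Module`` system and an Adam optimizer.

Every operation stores a backward closure; gradients are accumulated by a
topological sweep in :meth:`Tensor.backward`.  All arithmetic is float64 and
fully deterministic.  Correctness of each backward rule is checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "relu",
    "sigmoid",
    "concat",
    "conv2d",
    "maxpool2d",
    "upsample_bilinear",
    "softmax",
    "take_class",
    "Module",
    "Conv2d",
    "Linear",
    "Adam",
]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference fast path)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def _needs_graph(self) -> bool:
        return _grad_enabled and (self.requires_grad or bool(self._parents))

    def backward(self) -> None:
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._parents:
            def bw():
                if self._needs_graph():
                    self._accum(_unbroadcast(out.grad, self.shape))
                if other._needs_graph():
                    other._accum(_unbroadcast(out.grad, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._parents:
            def bw():
                if self._needs_graph():
                    self._accum(_unbroadcast(out.grad * other.data, self.shape))
                if other._needs_graph():
                    other._accum(_unbroadcast(out.grad * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out._parents:
            def bw():
                if self._needs_graph():
                    self._accum(_unbroadcast(out.grad / other.data, self.shape))
                if other._needs_graph():
                    other._accum(_unbroadcast(
                        -out.grad * self.data / (other.data ** 2), other.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, expo: float):
        expo = float(expo)
        out = _make(self.data ** expo, (self,))
        if out._parents:
            def bw():
                if self._needs_graph():
                    base = np.where(self.data == 0.0, 1.0, self.data)
                    self._accum(out.grad * expo * base ** (expo - 1.0)
                                * (self.data != 0.0 if expo < 1.0 else 1.0))
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._parents:
            def bw():
                if self._needs_graph():
                    self._accum(_unbroadcast(out.grad @ np.swapaxes(other.data, -1, -2),
                                             self.shape))
                if other._needs_graph():
                    other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ out.grad,
                                              other.shape))
            out._backward = bw
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, shape):
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            def bw():
                self._accum(out.grad.reshape(self.shape))
            out._backward = bw
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._parents:
            def bw():
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)
            out._backward = bw
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def bw():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient routed to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        idx_exp = np.expand_dims(idx, axis)
        val = np.take_along_axis(self.data, idx_exp, axis=axis)
        out = _make(val if keepdims else np.squeeze(val, axis=axis), (self,))
        if out._parents:
            def bw():
                g = out.grad if keepdims else np.expand_dims(out.grad, axis)
                full = np.zeros_like(self.data)
                np.put_along_axis(full, idx_exp, g, axis=axis)
                self._accum(full)
            out._backward = bw
        return out

    # -- pointwise nonlinearities ----------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = _make(val, (self,))
        if out._parents:
            def bw():
                self._accum(out.grad * val)
            out._backward = bw
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            def bw():
                self._accum(out.grad / self.data)
            out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only inside the open interval."""
        out = _make(np.clip(self.data, lo, hi), (self,))
        if out._parents:
            mask = (self.data > lo) & (self.data < hi)
            def bw():
                self._accum(out.grad * mask)
            out._backward = bw
        return out


def _make(data: np.ndarray, parents) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p._needs_graph() for p in parents):
        out._parents = tuple(parents)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- functional ops -------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out._parents:
        mask = x.data > 0.0
        def bw():
            x._accum(out.grad * mask)
        out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    val = 1.0 / (1.0 + np.exp(-x.data))
    out = _make(val, (x,))
    if out._parents:
        def bw():
            x._accum(out.grad * val * (1.0 - val))
        out._backward = bw
    return out


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.shape[axis] for t in tensors]
        offs = np.cumsum([0] + sizes)
        def bw():
            for t, a, b in zip(tensors, offs[:-1], offs[1:]):
                if t._needs_graph():
                    sl = [slice(None)] * out.ndim
                    sl[axis] = slice(a, b)
                    t._accum(out.grad[tuple(sl)])
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _make(s, (x,))
    if out._parents:
        def bw():
            g = out.grad
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))
        out._backward = bw
    return out


def take_class(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Gather per-pixel probability of the true class.

    probs: (N, K, H, W); labels: int array (N, H, W) -> (N, H, W).
    """
    probs = as_tensor(probs)
    idx = labels[:, None].astype(np.int64)
    val = np.take_along_axis(probs.data, idx, axis=1)[:, 0]
    out = _make(val, (probs,))
    if out._parents:
        def bw():
            full = np.zeros_like(probs.data)
            np.put_along_axis(full, idx, out.grad[:, None], axis=1)
            probs._accum(full)
        out._backward = bw
    return out


# -- convolution ----------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, h, w), (s[0], s[1], s[2], s[3], s[2], s[3]))
    return win.reshape(n, c * kh * kw, h * w)


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    d6 = dcols.reshape(n, c, kh, kw, h, w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for u in range(kh):
        for v in range(kw):
            dxp[:, :, u:u + h, v:v + w] += d6[:, :, u, v]
    return dxp[:, :, pad:pad + h, pad:pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, pad: int) -> Tensor:
    """Stride-1 'same' 2-D convolution (cross-correlation), NCHW layout."""
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    cols = _im2col(x.data, kh, kw, pad)                       # (N, C*kk, L)
    wm = weight.data.reshape(cout, cin * kh * kw)
    val = (wm @ cols).reshape(n, cout, h, w) + bias.data[None, :, None, None]
    out = _make(val, (x, weight, bias))
    if out._parents:
        def bw():
            g = out.grad.reshape(n, cout, h * w)
            if weight._needs_graph():
                dw = np.einsum("nfl,ncl->fc", g, cols)
                weight._accum(dw.reshape(weight.shape))
            if bias._needs_graph():
                bias._accum(out.grad.sum(axis=(0, 2, 3)))
            if x._needs_graph():
                dcols = np.matmul(wm.T, g)                    # (N, C*kk, L)
                x._accum(_col2im(dcols, x.shape, kh, kw, pad))
        out._backward = bw
    return out


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2d requires even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = np.argmax(xr, axis=-1)
    val = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = _make(val, (x,))
    if out._parents:
        def bw():
            g = np.zeros_like(xr)
            np.put_along_axis(g, idx[..., None], out.grad[..., None], axis=-1)
            g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accum(g.reshape(n, c, h, w))
        out._backward = bw
    return out


_interp_cache: dict = {}


def _interp_matrix(n_in: int, factor: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (align_corners=False)."""
    key = (n_in, factor)
    if key not in _interp_cache:
        n_out = n_in * factor
        m = np.zeros((n_out, n_in))
        for i in range(n_out):
            src = (i + 0.5) / factor - 0.5
            src = min(max(src, 0.0), n_in - 1.0)
            i0 = int(np.floor(src))
            i1 = min(i0 + 1, n_in - 1)
            f = src - i0
            m[i, i0] += 1.0 - f
            m[i, i1] += f
        _interp_cache[key] = m
    return _interp_cache[key]


def upsample_bilinear(x: Tensor, factor: int = 2) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.shape
    mh = _interp_matrix(h, factor)
    mw = _interp_matrix(w, factor)
    val = np.einsum("oh,nchw->ncow", mh, x.data)
    val = np.einsum("pw,ncow->ncop", mw, val)
    out = _make(val, (x,))
    if out._parents:
        def bw():
            # transpose of the separable linear map: dx = Mh^T . grad . Mw
            g = np.tensordot(out.grad, mw, axes=([3], [0]))   # (n, c, Ho, Win)
            g = np.tensordot(g, mh, axes=([2], [0]))          # (n, c, Win, Hin)
            x._accum(g.transpose(0, 1, 3, 2))
        out._backward = bw
    return out


# -- modules --------------------------------------------------------------

class Module:
    """Minimal container; parameters are discovered from attributes."""

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)

    def _children(self):
        for name, val in vars(self).items():
            yield name, val

    def named_parameters(self, prefix: str = ""):
        for name, val in self._children():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for '{name}': checkpoint {arr.shape}, "
                    f"model {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 pad: int | None = None):
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.pad = k // 2 if pad is None else pad

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.pad)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, std, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Adam:
    """Adam optimizer; per-parameter state keyed by identity so the
    trainable set can change between training phases without losing state."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._state: dict[int, list] = {}

    def set_params(self, params) -> None:
        self.params = list(params)

    def step(self) -> None:
        for p in self.params:
            if p.grad is None:
                continue
            st = self._state.get(id(p))
            if st is None:
                st = [np.zeros_like(p.data), np.zeros_like(p.data), 0]
                self._state[id(p)] = st
            m, v, t = st
            t += 1
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            st[2] = t
            mhat = m / (1 - self.b1 ** t)
            vhat = v / (1 - self.b2 ** t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
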