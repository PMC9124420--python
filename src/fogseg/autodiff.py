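"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation networks in :mod:`fogseg.nn` are small, fully convolutional
models; they are trained here with a compact tape-based autodiff engine rather
than a general deep-learning framework.  Only the operations those models need
are provided, each with a hand-derived backward pass (verified against central
finite differences in the test-suite):

* broadcast elementwise arithmetic, ReLU, log/exp/abs/clip/minimum,
* reductions (sum/mean), axis mean-pooling, slicing, concatenation,
* a linear map over the trailing axis,
* fused dilated temporal convolution over ``[B, T, M, C]`` feature maps,
* fused partitioned graph convolution with learnable edge masks,
* masked batch normalization (train/eval modes with running statistics),
* a fused LSTM step-loop (forward or time-reversed) with manual BPTT,
* softmax over the trailing axis.

All tensors are float32 by default.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` via topological traversal.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- basic protocol ----------------------------------------------------
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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.requires_grad:  # leaf parameter
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                grads[key] = grads[key] + pg if key in grads else pg

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division is not supported")
        return mul(self, 1.0 / float(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._backward is not None for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    if g.shape == tuple(shape):
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- elementwise ---------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _node(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _node(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(g * b.data, a.shape),
                            _unbroadcast(g * a.data, b.shape)))


def relu(x) -> Tensor:
    x = astensor(x)
    out = np.maximum(x.data, 0)
    return _node(out, (x,), lambda g: (g * (x.data > 0),))


def log(x) -> Tensor:
    x = astensor(x)
    return _node(np.log(x.data), (x,), lambda g: (g / x.data,))


def exp(x) -> Tensor:
    x = astensor(x)
    out = np.exp(x.data)
    return _node(out, (x,), lambda g: (g * out,))


def tabs(x) -> Tensor:
    x = astensor(x)
    return _node(np.abs(x.data), (x,), lambda g: (g * np.sign(x.data),))


def square(x) -> Tensor:
    x = astensor(x)
    return _node(x.data ** 2, (x,), lambda g: (2.0 * g * x.data,))


def clip_min(x, lo: float) -> Tensor:
    """max(x, lo); subgradient 0 where clipped."""
    x = astensor(x)
    out = np.maximum(x.data, lo)
    return _node(out, (x,), lambda g: (g * (x.data > lo),))


def minimum(x, hi: float) -> Tensor:
    """min(x, hi); subgradient 0 where truncated."""
    x = astensor(x)
    out = np.minimum(x.data, hi)
    return _node(out, (x,), lambda g: (g * (x.data < hi),))


# -- shape / reduction ---------------------------------------------------


def getitem(x, idx) -> Tensor:
    x = astensor(x)

    def backward(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        return (gx,)

    return _node(x.data[idx], (x,), backward)


def reshape(x, shape) -> Tensor:
    x = astensor(x)
    return _node(x.data.reshape(shape), (x,),
                 lambda g: (g.reshape(x.shape),))


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def tsum(x, axis=None, keepdims=False) -> Tensor:
    x = astensor(x)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, x.shape).copy(),)
        gg = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(gg, x.shape).copy(),)

    return _node(x.data.sum(axis=axis, keepdims=keepdims), (x,), backward)


def tmean(x, axis=None, keepdims=False) -> Tensor:
    x = astensor(x)
    n = x.data.size if axis is None else np.prod(
        [x.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(x, axis, keepdims), 1.0 / float(n))


# -- linear algebra -------------------------------------------------------


def linear(x, w, b=None) -> Tensor:
    """y = x @ w (+ b) over the trailing axis; x [..., Cin], w [Cin, Cout]."""
    x, w = astensor(x), astensor(w)
    out = x.data @ w.data

    def backward(g):
        gx = g @ w.data.T
        g2 = g.reshape(-1, g.shape[-1])
        x2 = x.data.reshape(-1, x.shape[-1])
        gw = x2.T @ g2
        return (gx, gw.astype(w.data.dtype))

    y = _node(out, (x, w), backward)
    if b is not None:
        y = add(y, b)
    return y


def softmax(x, axis: int = -1) -> Tensor:
    x = astensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return _node(out, (x,), backward)


# -- fused network ops ----------------------------------------------------


def dilated_conv_time(x, w, b, dilation: int, causal: bool = False) -> Tensor:
    """Dilated 1-D convolution along the time axis of ``x [B, T, M, C_in]``.

    ``w`` has shape ``[k, C_in, C_out]``.  Acausal mode pads
    ``(k-1)*dilation/2`` zeros on each side (k must be odd); causal mode pads
    only on the left.  Output length equals input length.
    """
    x, w, b = astensor(x), astensor(w), astensor(b)
    k = w.shape[0]
    d = int(dilation)
    total = (k - 1) * d
    if causal:
        pad_l, pad_r = total, 0
    else:
        if k % 2 == 0:
            raise ValueError("acausal convolution requires an odd kernel size")
        pad_l = pad_r = total // 2
    B, T, M, Cin = x.shape
    xp = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0), (0, 0)))
    out = np.broadcast_to(b.data, (B, T, M, w.shape[2])).copy()
    for j in range(k):
        out += xp[:, j * d: j * d + T] @ w.data[j]

    def backward(g):
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp)
        g2 = g.reshape(-1, g.shape[-1])
        for j in range(k):
            sl = xp[:, j * d: j * d + T]
            gw[j] = sl.reshape(-1, Cin).T @ g2
            gxp[:, j * d: j * d + T] += g @ w.data[j].T
        gx = gxp[:, pad_l: pad_l + T] if total else gxp
        gb = g.sum(axis=(0, 1, 2))
        return (gx, gw, gb)

    return _node(out, (x, w, b), backward)


def graph_conv(x, adjacency: np.ndarray, edge_mask, w, b) -> Tensor:
    """Partitioned spatial graph convolution.

    ``x [B, T, N, C_in]``; ``adjacency [P, N, N]`` fixed normalized partition
    matrices; ``edge_mask [P, N, N]`` learnable multiplicative mask;
    ``w [P, C_in, C_out]``.  Computes ``sum_p (A_p * M_p) x W_p + b``.
    """
    x, edge_mask, w, b = astensor(x), astensor(edge_mask), astensor(w), astensor(b)
    A = np.asarray(adjacency, dtype=x.data.dtype)
    P, N = A.shape[:2]
    S = A * edge_mask.data                             # [P, N, N]
    out = np.einsum("puv,btvc,pcd->btud", S, x.data, w.data, optimize=True)
    out += b.data

    def backward(g):
        B, T = g.shape[:2]
        Cin, Cout = w.shape[1:]
        gw = np.empty_like(w.data)
        gmask = np.empty_like(edge_mask.data)
        gx = np.zeros_like(x.data)
        x2 = x.data.reshape(-1, Cin)
        # node axis as leading dim for the big mask-gradient GEMM
        xn = np.ascontiguousarray(
            x.data.transpose(2, 0, 1, 3)).reshape(N, -1)
        for p in range(P):
            u = g @ w.data[p].T                        # dL/d(S_p x)  [B,T,N,Cin]
            gx += np.matmul(S[p].T, u)
            v = np.matmul(S[p].T, g)                   # [B,T,N,Cout]
            gw[p] = x2.T @ v.reshape(-1, Cout)
            un = np.ascontiguousarray(u.transpose(2, 0, 1, 3)).reshape(N, -1)
            gmask[p] = A[p] * (un @ xn.T)
        gb = g.sum(axis=(0, 1, 2))
        return (gx, gmask, gw, gb)

    return _node(out, (x, edge_mask, w, b), backward)


def batch_norm(x, gamma, beta, mask=None, running_mean=None, running_var=None,
               momentum: float = 0.1, training: bool = True,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization of ``x [B, T, M, C]``.

    ``mask [B, T]`` marks valid (non-padding) samples; statistics are computed
    over valid entries only.  In training mode batch statistics are used and
    the running buffers (plain numpy arrays) are updated in place; in eval
    mode the running statistics are used, making the op pointwise.
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    B, T, M, C = x.shape
    mk4 = None
    if mask is not None:
        mk4 = np.asarray(mask, dtype=x.data.dtype)[:, :, None, None]
    if training:
        if mk4 is None:
            m = B * T * M
            xm = x.data
        else:
            m = float(np.asarray(mask).sum()) * M
            xm = x.data * mk4
        s1 = np.einsum("btmc->c", xm, optimize=True)
        s2 = np.einsum("btmc,btmc->c", xm, xm, optimize=True)
        mu = s1 / m
        var = np.maximum(s2 / m - mu * mu, 0.0)
        if running_mean is not None:
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            running_var *= 1.0 - momentum
            running_var += momentum * var
    else:
        mu = running_mean if running_mean is not None else np.zeros(C, x.data.dtype)
        var = running_var if running_var is not None else np.ones(C, x.data.dtype)
    invstd = (1.0 / np.sqrt(var + eps)).astype(x.data.dtype)
    xhat = x.data * invstd
    xhat -= (mu * invstd).astype(x.data.dtype)
    if mk4 is not None:
        xhat *= mk4
    out = xhat * gamma.data
    out += beta.data
    if mk4 is not None:
        out *= mk4

    def backward(g):
        if mk4 is not None:
            g = g * mk4
        ggamma = np.einsum("btmc,btmc->c", g, xhat, optimize=True)
        gbeta = np.einsum("btmc->c", g, optimize=True)
        gx = g * gamma.data
        if training:
            s1g = np.einsum("btmc->c", gx, optimize=True)
            s2g = np.einsum("btmc,btmc->c", gx, xhat, optimize=True)
            gx -= s1g / m
            gx -= xhat * (s2g / m)
            gx *= invstd
            if mk4 is not None:
                gx *= mk4
        else:
            gx *= invstd
        return (gx, ggamma, gbeta)

    return _node(out, (x, gamma, beta), backward)


def lstm(x, w_ih, w_hh, b, reverse: bool = False) -> Tensor:
    """Single LSTM layer over ``x [B, T, C_in]`` returning hidden states [B, T, H].

    ``w_ih [C_in, 4H]``, ``w_hh [H, 4H]``, ``b [4H]``; gate order i, f, g, o.
    ``reverse=True`` processes the sequence back-to-front (backward layer of a
    bidirectional model).  Backward pass is hand-rolled BPTT.
    """
    x, w_ih, w_hh, b = astensor(x), astensor(w_ih), astensor(w_hh), astensor(b)
    B, T, Cin = x.shape
    H = w_hh.shape[0]
    xd = x.data[:, ::-1] if reverse else x.data
    h = np.zeros((B, H), dtype=xd.dtype)
    c = np.zeros((B, H), dtype=xd.dtype)
    hs = np.empty((B, T, H), dtype=xd.dtype)
    cache = []
    for t in range(T):
        z = xd[:, t] @ w_ih.data + h @ w_hh.data + b.data
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        gg = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_prev = c
        c = f * c_prev + i * gg
        tc = np.tanh(c)
        h_prev = h
        h = o * tc
        hs[:, t] = h
        cache.append((i, f, gg, o, c_prev, tc, h_prev))
    out = hs[:, ::-1].copy() if reverse else hs

    def backward(g):
        gd = g[:, ::-1] if reverse else g
        gx = np.zeros_like(xd)
        gwih = np.zeros_like(w_ih.data)
        gwhh = np.zeros_like(w_hh.data)
        gb = np.zeros_like(b.data)
        dh = np.zeros((B, H), dtype=xd.dtype)
        dc = np.zeros((B, H), dtype=xd.dtype)
        for t in range(T - 1, -1, -1):
            i, f, gg, o, c_prev, tc, h_prev = cache[t]
            dh = dh + gd[:, t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc ** 2)
            di = dc * gg
            dgg = dc * i
            df = dc * c_prev
            dc = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dgg * (1 - gg ** 2), do * o * (1 - o)], axis=1)
            gx[:, t] = dz @ w_ih.data.T
            dh = dz @ w_hh.data.T
            gwih += xd[:, t].T @ dz
            gwhh += h_prev.T @ dz
            gb += dz.sum(axis=0)
        if reverse:
            gx = gx[:, ::-1].copy()
        return (gx, gwih, gwhh, gb)

    return _node(out, (x, w_ih, w_hh, b), backward)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


# -- optimizer -------------------------------------------------------------


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 5e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
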