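"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the temporal-convolution autoencoder and the
CNN-LSTM selective classifier need: broadcast arithmetic, matmul, causal
dilated 1-D convolution, non-overlapping average pooling, nearest-neighbour
up-sampling, elementwise nonlinearities, reductions, slicing and a fused
softmax cross-entropy.  Tensors keep the dtype they are given (float32 for
training throughput, float64 for finite-difference gradient checks).

Large intermediate buffers are drawn from a shape-keyed :class:`BufferPool`
when one is enabled: training graphs allocate identical shapes every step, so
after the first minibatch no new pages are faulted in.  Trainers call
``pool.release_all()`` once the step's gradients have been consumed.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = True


class BufferPool:
    """Exact-shape free-list allocator for transient graph buffers."""

    def __init__(self, min_bytes: int = 1 << 16):
        self.min_bytes = min_bytes
        self._free: dict[tuple, list[np.ndarray]] = {}
        self._used: dict[int, tuple[tuple, np.ndarray]] = {}
        self.enabled = False

    def acquire(self, shape, dtype) -> np.ndarray:
        dtype = np.dtype(dtype)
        if not self.enabled or int(np.prod(shape)) * dtype.itemsize < self.min_bytes:
            return np.empty(shape, dtype)
        key = (tuple(shape), dtype.str)
        free = self._free.get(key)
        arr = free.pop() if free else np.empty(shape, dtype)
        self._used[id(arr)] = (key, arr)
        return arr

    def recycle(self, arr: np.ndarray) -> None:
        """Return one buffer early (e.g. a consumed gradient): caps backward
        peak memory at the live frontier instead of the whole graph."""
        entry = self._used.pop(id(arr), None)
        if entry is not None:
            self._free.setdefault(entry[0], []).append(entry[1])

    def release_all(self) -> None:
        """Return every buffer handed out since the last release.

        Only call once no live Tensor references pool-backed data — i.e.
        after the graph of the current step has been dropped.
        """
        for key, arr in self._used.values():
            self._free.setdefault(key, []).append(arr)
        self._used.clear()

    def clear(self) -> None:
        """Drop all cached buffers (frees memory between pipeline stages)."""
        self._free.clear()
        self._used.clear()

    @contextlib.contextmanager
    def active(self):
        prev = self.enabled
        self.enabled = True
        try:
            yield self
        finally:
            self.enabled = prev


pool = BufferPool()


def _new(shape, dtype) -> np.ndarray:
    return pool.acquire(shape, dtype)


def _new_zeros(shape, dtype) -> np.ndarray:
    out = pool.acquire(shape, dtype)
    out.fill(0)
    return out


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data)
        if self.data.dtype.kind in "iub":
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward: Callable[[], None] | None = None
        self._prev = _prev if _GRAD_ENABLED else ()
        if not _GRAD_ENABLED:
            self.requires_grad = False

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            buf = _new(self.data.shape, self.data.dtype)
            np.copyto(buf, g)
            self.grad = buf
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad only on scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs include per-timestep LSTM nodes
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad:
                node._backward()
            # a non-leaf node's gradient is fully consumed once its backward
            # has run; hand the buffer back so the pool can reuse it within
            # this same pass (leaves keep grads for the optimizer)
            if node._prev and node.grad is not None:
                pool.recycle(node.grad)
                node.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __pow__(self, p):
        return power(self, p)

    def __neg__(self):
        return mul(self, _const(-1.0))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _const(x) -> Tensor:
    return Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `g` down to `shape` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _binop_out(a: np.ndarray, b: np.ndarray, ufunc) -> np.ndarray:
    shape = np.broadcast_shapes(a.shape, b.shape)
    out = _new(shape, np.result_type(a.dtype, b.dtype))
    return ufunc(a, b, out=out)


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(_binop_out(a.data, b.data, np.add), _prev=(a, b))
    if out.requires_grad:
        def _backward():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad, b.data.shape))
        out._backward = _backward
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(_binop_out(a.data, b.data, np.subtract), _prev=(a, b))
    if out.requires_grad:
        def _backward():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad, a.data.shape))
            if b.requires_grad:
                b._accum(-_unbroadcast(out.grad, b.data.shape))
        out._backward = _backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(_binop_out(a.data, b.data, np.multiply), _prev=(a, b))
    if out.requires_grad:
        def _backward():
            if a.requires_grad:
                a._accum(_unbroadcast(_binop_out(out.grad, b.data, np.multiply),
                                      a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(_binop_out(out.grad, a.data, np.multiply),
                                      b.data.shape))
        out._backward = _backward
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(_binop_out(a.data, b.data, np.divide), _prev=(a, b))
    if out.requires_grad:
        def _backward():
            if a.requires_grad:
                a._accum(_unbroadcast(_binop_out(out.grad, b.data, np.divide),
                                      a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-out.grad * a.data / b.data**2, b.data.shape))
        out._backward = _backward
    return out


def power(a: Tensor, p: float) -> Tensor:
    y = _new(a.data.shape, a.data.dtype)
    np.power(a.data, p, out=y)
    out = Tensor(y, _prev=(a,))
    if out.requires_grad:
        def _backward():
            a._accum(out.grad * p * a.data ** (p - 1))
        out._backward = _backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, _prev=(a, b))
    if out.requires_grad:
        def _backward():
            g = out.grad
            if a.requires_grad:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))
        out._backward = _backward
    return out


def relu(a: Tensor) -> Tensor:
    y = _new(a.data.shape, a.data.dtype)
    np.maximum(a.data, 0, out=y)
    out = Tensor(y, _prev=(a,))
    if out.requires_grad:
        def _backward():
            mask = _new(a.data.shape, np.bool_)
            np.greater(y, 0, out=mask)
            g = _new(a.data.shape, a.data.dtype)
            np.multiply(out.grad, mask, out=g)
            a._accum(g)
        out._backward = _backward
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = _new(a.data.shape, a.data.dtype)
    np.clip(a.data, -60, 60, out=s)
    np.negative(s, out=s)
    np.exp(s, out=s)
    s += 1.0
    np.reciprocal(s, out=s)
    out = Tensor(s, _prev=(a,))
    if out.requires_grad:
        def _backward():
            a._accum(out.grad * s * (1 - s))
        out._backward = _backward
    return out


def tanh(a: Tensor) -> Tensor:
    t = _new(a.data.shape, a.data.dtype)
    np.tanh(a.data, out=t)
    out = Tensor(t, _prev=(a,))
    if out.requires_grad:
        def _backward():
            a._accum(out.grad * (1 - t * t))
        out._backward = _backward
    return out


def exp(a: Tensor) -> Tensor:
    e = _new(a.data.shape, a.data.dtype)
    np.exp(a.data, out=e)
    out = Tensor(e, _prev=(a,))
    if out.requires_grad:
        def _backward():
            a._accum(out.grad * e)
        out._backward = _backward
    return out


def log(a: Tensor) -> Tensor:
    y = _new(a.data.shape, a.data.dtype)
    np.log(a.data, out=y)
    out = Tensor(y, _prev=(a,))
    if out.requires_grad:
        def _backward():
            a._accum(out.grad / a.data)
        out._backward = _backward
    return out


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _prev=(a,))
    if out.requires_grad:
        def _backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            buf = _new(a.data.shape, a.data.dtype)
            buf[...] = g
            a._accum(buf)
        out._backward = _backward
    return out


def mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), _const(1.0 / n))


def maximum0(a: Tensor) -> Tensor:
    """max(0, a) elementwise — the hinge inside the coverage penalty."""
    return relu(a)


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), _prev=(a,))
    if out.requires_grad:
        def _backward():
            a._accum(out.grad.reshape(a.data.shape))
        out._backward = _backward
    return out


def transpose(a: Tensor, axes) -> Tensor:
    out = Tensor(a.data.transpose(axes), _prev=(a,))
    if out.requires_grad:
        inv = np.argsort(axes)
        def _backward():
            a._accum(out.grad.transpose(inv))
        out._backward = _backward
    return out


def _is_advanced(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return any(isinstance(i, (list, np.ndarray)) for i in items)


def getitem(a: Tensor, idx) -> Tensor:
    out = Tensor(a.data[idx], _prev=(a,))
    if out.requires_grad:
        def _backward():
            g = _new_zeros(a.data.shape, a.data.dtype)
            if _is_advanced(idx):
                np.add.at(g, idx, out.grad)
            else:  # basic slices touch each element at most once
                g[idx] += out.grad
            a._accum(g)
        out._backward = _backward
    return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def _backward():
            parts = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(g)
        out._backward = _backward
    return out


# ---------------------------------------------------------------------------
# network-level ops
# ---------------------------------------------------------------------------

def conv1d_causal(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Causal dilated 1-D convolution, channels-last.

    x: (N, L, C); w: (K, C, F); b: (F,).  Output (N, L, F); output step t sees
    inputs at t, t-d, ..., t-(K-1)d only (left zero padding), so the layer is
    causal for every dilation.  One matmul per kernel tap on a shifted view of
    the padded input — no im2col buffer.
    """
    N, L, C = x.data.shape
    K, Cw, F = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    pad = (K - 1) * dilation
    dt = x.data.dtype
    xp = _new((N, L + pad, C), dt)
    xp[:, :pad, :] = 0
    xp[:, pad:, :] = x.data
    y = _new((N, L, F), dt)
    tmp = _new((N, L, F), dt)
    # kernel tap t multiplies the input shifted (K-1-t)*dilation steps into
    # the past; with left padding that is the slice starting at t*dilation
    np.matmul(xp[:, 0:L, :], w.data[0], out=y)
    for t in range(1, K):
        np.matmul(xp[:, t * dilation:t * dilation + L, :], w.data[t], out=tmp)
        y += tmp
    y += b.data
    out = Tensor(y, _prev=(x, w, b))
    if out.requires_grad:
        def _backward():
            go = out.grad
            go2 = go.reshape(N * L, F)
            if b.requires_grad:
                b._accum(go2.sum(axis=0))
            if w.requires_grad:
                dw = np.empty_like(w.data)
                xs = _new((N * L, C), dt)
                for t in range(K):
                    xs.reshape(N, L, C)[...] = xp[:, t * dilation:t * dilation + L, :]
                    np.matmul(xs.T, go2, out=dw[t])
                w._accum(dw)
            if x.requires_grad:
                dxp = _new_zeros(xp.shape, dt)
                dtmp = _new((N, L, C), dt)
                for t in range(K):
                    np.matmul(go, w.data[t].T, out=dtmp)
                    dxp[:, t * dilation:t * dilation + L, :] += dtmp
                x._accum(dxp[:, pad:, :])
        out._backward = _backward
    return out


def avg_pool1d(x: Tensor, m: int) -> Tensor:
    """Non-overlapping average pooling along the time axis of (N, L, C);
    a trailing remainder shorter than m is dropped."""
    N, L, C = x.data.shape
    Lo = L // m
    xt = x.data[:, :Lo * m, :].reshape(N, Lo, m, C)
    out = Tensor(xt.mean(axis=2), _prev=(x,))
    if out.requires_grad:
        def _backward():
            g = _new_zeros(x.data.shape, x.data.dtype)
            g[:, :Lo * m, :].reshape(N, Lo, m, C)[...] = \
                (out.grad / m)[:, :, None, :]
            x._accum(g)
        out._backward = _backward
    return out


def upsample_repeat(x: Tensor, m: int) -> Tensor:
    """Nearest-neighbour up-sampling along the time axis: each step of
    (N, L, C) repeated m times."""
    N, L, C = x.data.shape
    y = _new((N, L * m, C), x.data.dtype)
    y.reshape(N, L, m, C)[...] = x.data[:, :, None, :]
    out = Tensor(y, _prev=(x,))
    if out.requires_grad:
        def _backward():
            x._accum(out.grad.reshape(N, L, m, C).sum(axis=2))
        out._backward = _backward
    return out


def lstm_last_hidden(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor) -> Tensor:
    """Single-layer LSTM over (N, T, F); returns the final hidden state.

    Fused op: the whole recurrence is one graph node with hand-written
    backpropagation-through-time, instead of ~15 primitive nodes per step.
    Gate layout along the last axis of the (F, 4H) / (H, 4H) weights:
    input, forget, cell, output.
    """
    N, T, F = x.data.shape
    H = wh.data.shape[0]
    dt = x.data.dtype

    def sig(a):
        return 1.0 / (1.0 + np.exp(-np.clip(a, -60, 60)))

    xw = x.data.reshape(N * T, F) @ wx.data  # all input projections at once
    xw = xw.reshape(N, T, 4 * H)
    h = np.zeros((N, H), dtype=dt)
    c = np.zeros((N, H), dtype=dt)
    gates = np.empty((T, N, 4 * H), dtype=dt)   # post-activation i,f,g,o
    cells = np.empty((T + 1, N, H), dtype=dt)   # c_{t-1} per step
    hiddens = np.empty((T + 1, N, H), dtype=dt)
    cells[0] = c
    hiddens[0] = h
    for t in range(T):
        a = xw[:, t, :] + h @ wh.data + b.data
        i = sig(a[:, 0:H])
        f = sig(a[:, H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = sig(a[:, 3 * H:4 * H])
        c = f * c + i * g
        h = o * np.tanh(c)
        gates[t, :, 0:H] = i
        gates[t, :, H:2 * H] = f
        gates[t, :, 2 * H:3 * H] = g
        gates[t, :, 3 * H:4 * H] = o
        cells[t + 1] = c
        hiddens[t + 1] = h
    out = Tensor(h.copy(), _prev=(x, wx, wh, b))
    if out.requires_grad:
        def _backward():
            dh = out.grad.astype(dt, copy=True)
            dc = np.zeros((N, H), dtype=dt)
            dwx = np.zeros_like(wx.data)
            dwh = np.zeros_like(wh.data)
            db = np.zeros_like(b.data)
            da_all = np.empty((N, T, 4 * H), dtype=dt) if x.requires_grad else None
            for t in range(T - 1, -1, -1):
                i = gates[t, :, 0:H]
                f = gates[t, :, H:2 * H]
                g = gates[t, :, 2 * H:3 * H]
                o = gates[t, :, 3 * H:4 * H]
                tc = np.tanh(cells[t + 1])
                do = dh * tc
                dc = dc + dh * o * (1 - tc * tc)
                di = dc * g
                dg = dc * i
                df = dc * cells[t]
                da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                     dg * (1 - g * g), do * o * (1 - o)],
                                    axis=1)
                dwh += hiddens[t].T @ da
                db += da.sum(axis=0)
                if da_all is not None:
                    da_all[:, t, :] = da
                else:
                    dwx += x.data[:, t, :].T @ da
                dh = da @ wh.data.T
                dc = dc * f
            if da_all is not None:
                da2 = da_all.reshape(N * T, 4 * H)
                x._accum((da2 @ wx.data.T).reshape(N, T, F))
                dwx = x.data.reshape(N * T, F).T @ da2
            else:
                # dwx accumulated per step above
                pass
            if wx.requires_grad:
                wx._accum(dwx)
            if wh.requires_grad:
                wh._accum(dwh)
            if b.requires_grad:
                b._accum(db)
        out._backward = _backward
    return out


def softmax_cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    """Per-sample cross-entropy of softmax(logits) against integer labels.

    Returns a length-N tensor (NOT averaged): the selective risk weights each
    sample's loss by its own confidence score before normalising.
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    losses = -(z - zmax)[np.arange(n), y] + np.log(ez.sum(axis=1))
    out = Tensor(losses, _prev=(logits,))
    if out.requires_grad:
        def _backward():
            dp = p.copy()
            dp[np.arange(n), y] -= 1.0
            logits._accum(dp * out.grad[:, None])
        out._backward = _backward
    return out


def softmax(logits: Tensor) -> Tensor:
    z = logits.data
    ez = np.exp(z - z.max(axis=1, keepdims=True))
    p = ez / ez.sum(axis=1, keepdims=True)
    out = Tensor(p, _prev=(logits,))
    if out.requires_grad:
        def _backward():
            g = out.grad
            dot = (g * p).sum(axis=1, keepdims=True)
            logits._accum(p * (g - dot))
        out._backward = _backward
    return out
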