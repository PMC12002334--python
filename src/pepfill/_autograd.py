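"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for a recurrent encoder-decoder: elementwise ops,
2-D matmul, embedding lookup, column slicing, time stacking, batched
attention contractions, and a masked cross-entropy.  A global ``no_grad``
switch turns every op into a plain NumPy computation for inference.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True

#: compute dtype; float32 roughly halves training time, float64 is used by
#: the finite-difference gradient checks
DTYPE = np.float32


@contextmanager
def compute_dtype(dtype):
    global DTYPE
    prev = DTYPE
    DTYPE = dtype
    try:
        yield
    finally:
        DTYPE = prev


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        """Reverse-mode sweep from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs have thousands of nodes
            node, processed = stack.pop()
            if id(node) in seen:
                continue
            if processed:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen and p.requires_grad:
                        stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # convenience arithmetic
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _make(data, parents, backward):
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    t = Tensor(data, requires_grad=req)
    if req:
        t._parents = tuple(p for p in parents if p.requires_grad)
        t._backward = backward
    return t


def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(grad):
        if a.requires_grad:
            a._accum(_unbroadcast(grad, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(grad, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(grad):
        if a.requires_grad:
            a._accum(_unbroadcast(grad * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(grad * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(grad):
        if a.requires_grad:
            a._accum(grad @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ grad)

    return _make(out_data, (a, b), backward)


def sigmoid(a):
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

    def backward(grad):
        a._accum(grad * s * (1 - s))

    return _make(s, (a,), backward)


def tanh(a):
    a = _wrap(a)
    t_ = np.tanh(a.data)

    def backward(grad):
        a._accum(grad * (1 - t_ * t_))

    return _make(t_, (a,), backward)


def slice_cols(a, start, end):
    a = _wrap(a)
    out_data = a.data[:, start:end]

    def backward(grad):
        g = np.zeros_like(a.data)
        g[:, start:end] = grad
        a._accum(g)

    return _make(out_data, (a,), backward)


def embedding(weight, idx):
    """Row lookup ``weight[idx]`` with scatter-add backward."""
    weight = _wrap(weight)
    idx = np.asarray(idx, dtype=np.int64)
    out_data = weight.data[idx]

    def backward(grad):
        g = np.zeros_like(weight.data)
        np.add.at(g, idx, grad)
        weight._accum(g)

    return _make(out_data, (weight,), backward)


def stack_time(tensors):
    """List of (B, D) -> (B, T, D)."""
    ts = [_wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in ts], axis=1)

    def backward(grad):
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accum(grad[:, i, :])

    return _make(out_data, tuple(ts), backward)


def attn_scores(enc, h):
    """(B,T,D),(B,D) -> (B,T) batched dot products."""
    enc, h = _wrap(enc), _wrap(h)
    out_data = np.einsum("btd,bd->bt", enc.data, h.data)

    def backward(grad):
        if enc.requires_grad:
            enc._accum(np.einsum("bt,bd->btd", grad, h.data))
        if h.requires_grad:
            h._accum(np.einsum("bt,btd->bd", grad, enc.data))

    return _make(out_data, (enc, h), backward)


def attn_context(alpha, enc):
    """(B,T),(B,T,D) -> (B,D) attention-weighted sum."""
    alpha, enc = _wrap(alpha), _wrap(enc)
    out_data = np.einsum("bt,btd->bd", alpha.data, enc.data)

    def backward(grad):
        if alpha.requires_grad:
            alpha._accum(np.einsum("bd,btd->bt", grad, enc.data))
        if enc.requires_grad:
            enc._accum(np.einsum("bt,bd->btd", alpha.data, grad))

    return _make(out_data, (alpha, enc), backward)


def masked_softmax(scores, mask):
    """Softmax over axis 1; positions where ``mask`` is 0 get zero weight."""
    scores = _wrap(scores)
    mask = np.asarray(mask, dtype=bool)
    z = np.where(mask, scores.data, -1e30)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z) * mask
    denom = e.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    p = e / denom

    def backward(grad):
        dot = (grad * p).sum(axis=1, keepdims=True)
        scores._accum(p * (grad - dot))

    return _make(p, (scores,), backward)


def log_softmax(logits):
    logits = _wrap(logits)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    out_data = z - lse

    def backward(grad):
        p = np.exp(out_data)
        logits._accum(grad - p * grad.sum(axis=-1, keepdims=True))

    return _make(out_data, (logits,), backward)


def nll_rows(logits, targets, mask):
    """Per-row negative log-likelihood of ``targets`` under ``logits``.

    logits (B,V), targets (B,), mask (B,) -> (B,); masked rows contribute 0.
    """
    logits = _wrap(logits)
    targets = np.asarray(targets, dtype=np.int64)
    mask = np.asarray(mask, dtype=DTYPE)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    rows = np.arange(len(targets))
    out_data = (lse - z[rows, targets]) * mask

    def backward(grad):
        p = np.exp(z - lse[:, None])
        p[rows, targets] -= 1.0
        logits._accum(p * (grad * mask)[:, None])

    return _make(out_data, (logits,), backward)


def total(a):
    """Sum of all elements -> scalar tensor."""
    a = _wrap(a)
    out_data = np.array(a.data.sum())

    def backward(grad):
        a._accum(np.broadcast_to(grad, a.shape).astype(a.data.dtype))

    return _make(out_data, (a,), backward)


def mean(a):
    a = _wrap(a)
    n = a.data.size
    out_data = np.array(a.data.mean())

    def backward(grad):
        a._accum(np.broadcast_to(grad / n, a.shape).astype(a.data.dtype))

    return _make(out_data, (a,), backward)


def concat_cols(tensors):
    ts = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=1)

    def backward(grad):
        start = 0
        for t in ts:
            width = t.shape[1]
            if t.requires_grad:
                t._accum(grad[:, start : start + width])
            start += width

    return _make(out_data, tuple(ts), backward)


class Adam:
    """Adam with optional inverse-sqrt warm-up schedule."""

    def __init__(self, params: dict, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 warmup_steps: int = 0):
        self.params = params
        self.base_lr = lr
        self.betas = betas
        self.eps = eps
        self.warmup = warmup_steps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def current_lr(self) -> float:
        if self.warmup <= 0:
            return self.base_lr
        step = max(self.t, 1)
        scale = min(step / self.warmup, (self.warmup / step) ** 0.5)
        return self.base_lr * scale

    def step(self, clip: float | None = 5.0):
        self.t += 1
        lr = self.current_lr()
        b1, b2 = self.betas
        if clip is not None:
            norm = np.sqrt(
                sum(
                    float((p.grad ** 2).sum())
                    for p in self.params.values()
                    if p.grad is not None
                )
            )
            if norm > clip:
                for p in self.params.values():
                    if p.grad is not None:
                        p.grad *= clip / norm
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


# -- fused ops for the recurrent model ---------------------------------------


def gru_step(x3d, t, h, Wx, Wh, b, mask_col=None):
    """One GRU step reading timestep ``t`` of a pre-embedded (B,T,E) input.

    Fused forward/backward of: z = sig(gxz+ghz), r = sig(gxr+ghr),
    n = tanh(gxn + r*ghn), h' = (1-z)*n + z*h; when ``mask_col`` (B,1) is
    given, padded rows keep their previous state.
    """
    x3d, h = _wrap(x3d), _wrap(h)
    Wx, Wh, b = _wrap(Wx), _wrap(Wh), _wrap(b)
    x = x3d.data[:, t, :]
    H = h.data.shape[1]
    gx = x @ Wx.data + b.data
    gh = h.data @ Wh.data
    z = 1.0 / (1.0 + np.exp(-np.clip(gx[:, :H] + gh[:, :H], -60, 60)))
    r = 1.0 / (1.0 + np.exp(-np.clip(gx[:, H:2*H] + gh[:, H:2*H], -60, 60)))
    ghn = gh[:, 2*H:]
    n = np.tanh(gx[:, 2*H:] + r * ghn)
    h_new = n + z * (h.data - n)
    if mask_col is not None:
        m = np.asarray(mask_col, dtype=x3d.data.dtype)
        out_data = m * h_new + (1 - m) * h.data
    else:
        m = None
        out_data = h_new

    def backward(grad):
        if m is not None:
            g_hnew = grad * m
            g_h_skip = grad * (1 - m)
        else:
            g_hnew = grad
            g_h_skip = 0.0
        dz = g_hnew * (h.data - n)
        dn = g_hnew * (1 - z)
        dh = g_hnew * z + g_h_skip
        dn_pre = dn * (1 - n * n)
        dr = dn_pre * ghn
        da_z = dz * z * (1 - z)
        da_r = dr * r * (1 - r)
        dgx = np.concatenate([da_z, da_r, dn_pre], axis=1)
        dgh = np.concatenate([da_z, da_r, dn_pre * r], axis=1)
        if Wx.requires_grad:
            Wx._accum(x.T @ dgx)
        if b.requires_grad:
            b._accum(dgx.sum(axis=0))
        if Wh.requires_grad:
            Wh._accum(h.data.T @ dgh)
        if h.requires_grad:
            h._accum(dh + dgh @ Wh.data.T)
        if x3d.requires_grad:
            # write straight into the slice: a fresh full-size zero buffer per
            # timestep would dominate the backward pass
            if x3d.grad is None:
                x3d.grad = np.zeros_like(x3d.data)
            x3d.grad[:, t, :] += dgx @ Wx.data.T

    return _make(out_data, (x3d, h, Wx, Wh, b), backward)


def attention(enc, h, W, mask):
    """Multiplicative attention: softmax((h W) . enc_t) -> context vector.

    enc (B,T,D), h (B,Dh), W (Dh,D), mask (B,T) -> ctx (B,D).
    """
    enc, h, W = _wrap(enc), _wrap(h), _wrap(W)
    mask = np.asarray(mask, dtype=bool)
    q = h.data @ W.data
    s = (enc.data @ q[:, :, None])[:, :, 0]
    z = np.where(mask, s, -1e30)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z) * mask
    denom = e.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    alpha = e / denom
    ctx = (alpha[:, None, :] @ enc.data)[:, 0]

    def backward(grad):
        dalpha = (enc.data @ grad[:, :, None])[:, :, 0]
        ds = alpha * (dalpha - (dalpha * alpha).sum(axis=1, keepdims=True))
        dq = np.einsum("bt,btd->bd", ds, enc.data)
        if enc.requires_grad:
            enc._accum(
                np.einsum("bt,bd->btd", alpha, grad)
                + np.einsum("bt,bd->btd", ds, q)
            )
        if h.requires_grad:
            h._accum(dq @ W.data.T)
        if W.requires_grad:
            W._accum(h.data.T @ dq)

    return _make(ctx, (enc, h, W), backward)


def affine2(a, b, W, bias):
    """[a ; b] @ W + bias without materializing the concatenation node."""
    a, b, W, bias = _wrap(a), _wrap(b), _wrap(W), _wrap(bias)
    da_ = a.data.shape[1]
    Wa, Wb = W.data[:da_], W.data[da_:]
    out_data = a.data @ Wa + b.data @ Wb + bias.data

    def backward(grad):
        if a.requires_grad:
            a._accum(grad @ Wa.T)
        if b.requires_grad:
            b._accum(grad @ Wb.T)
        if W.requires_grad:
            g = np.concatenate(
                [a.data.T @ grad, b.data.T @ grad], axis=0
            )
            W._accum(g)
        if bias.requires_grad:
            bias._accum(grad.sum(axis=0))

    return _make(out_data, (a, b, W, bias), backward)


def stack_pair_last(a, b):
    """Concatenate two (B,T,H) tensors along the last axis -> (B,T,2H)."""
    a, b = _wrap(a), _wrap(b)
    out_data = np.concatenate([a.data, b.data], axis=2)
    H = a.data.shape[2]

    def backward(grad):
        if a.requires_grad:
            a._accum(grad[:, :, :H])
        if b.requires_grad:
            b._accum(grad[:, :, H:])

    return _make(out_data, (a, b), backward)


def attention_seq(enc, hs, W, mask):
    """Attention for a whole decoded sequence at once.

    enc (B,T,D), hs (B,S,Dh), W (Dh,D), mask (B,T) -> ctx (B,S,D).
    Batched BLAS matmuls instead of per-step contractions.
    """
    enc, hs, W = _wrap(enc), _wrap(hs), _wrap(W)
    mask = np.asarray(mask, dtype=bool)
    q = hs.data @ W.data                      # (B,S,D)
    s = q @ enc.data.transpose(0, 2, 1)       # (B,S,T)
    z = np.where(mask[:, None, :], s, -1e30)
    z = z - z.max(axis=2, keepdims=True)
    e = np.exp(z) * mask[:, None, :]
    denom = e.sum(axis=2, keepdims=True)
    denom[denom == 0] = 1.0
    alpha = e / denom                         # (B,S,T)
    ctx = alpha @ enc.data                    # (B,S,D)

    def backward(grad):
        dalpha = grad @ enc.data.transpose(0, 2, 1)          # (B,S,T)
        ds = alpha * (dalpha - (dalpha * alpha).sum(axis=2, keepdims=True))
        dq = ds @ enc.data                                    # (B,S,D)
        if enc.requires_grad:
            enc._accum(
                alpha.transpose(0, 2, 1) @ grad
                + ds.transpose(0, 2, 1) @ q
            )
        if hs.requires_grad:
            hs._accum(dq @ W.data.T)
        if W.requires_grad:
            W._accum(
                np.einsum("bsd,bse->de", hs.data, dq)
            )

    return _make(ctx, (enc, hs, W), backward)


def reshape(a, shape):
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def backward(grad):
        a._accum(grad.reshape(a.shape))

    return _make(out_data, (a,), backward)


def sum_axis(a, axis):
    a = _wrap(a)
    out_data = a.data.sum(axis=axis)

    def backward(grad):
        a._accum(np.expand_dims(grad, axis).repeat(a.shape[axis], axis=axis))

    return _make(out_data, (a,), backward)
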