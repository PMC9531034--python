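"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape sufficient for backpropagation-through-time in this
package: elementwise arithmetic with broadcasting, exp/log/relu, the
layer matmul, per-neuron causal convolution, time stacking/slicing, and
a fused softmax-cross-entropy head.  Non-differentiable spike counts are
handled by composing a detached floor with a straight-through residual
(see `mapsnn.network`), so no special node type is needed here.

Every `Tensor` wraps a float ndarray; ops record parents and a closure
that scatters the output gradient back onto them.  `backward()` runs a
topological sweep.  This is intentionally eager and unoptimised — the
networks trained here are small.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- graph mechanics ------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=float), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() is defined for scalar outputs only")
        topo: List[Tensor] = []
        seen = set()

        def visit(node: "Tensor") -> None:
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise ops ------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / other.data ** 2)

        out._backward = bwd
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def relu(self) -> "Tensor":
        mask = (self.data > 0).astype(float)
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), _parents=(self,))
        out._backward = lambda g: self._accumulate(np.broadcast_to(g, self.data.shape))
        return out

    def sum_last(self) -> "Tensor":
        """Sum over the trailing (time) axis."""
        out = Tensor(self.data.sum(axis=-1), _parents=(self,))
        out._backward = lambda g: self._accumulate(
            np.repeat(g[..., None], self.data.shape[-1], axis=-1)
        )
        return out


# -- structured ops ------------------------------------------------------


def layer_matmul(W: Tensor, O: Tensor) -> Tensor:
    """``(n_out x n_in) @ (batch x n_in x T) -> (batch x n_out x T)``."""
    out = Tensor(np.einsum("oi,bit->bot", W.data, O.data), _parents=(W, O))

    def bwd(g):
        if W.requires_grad:
            W._accumulate(np.einsum("bot,bit->oi", g, O.data))
        if O.requires_grad:
            O._accumulate(np.einsum("oi,bot->bit", W.data, g))

    out._backward = bwd
    return out


def getcol(x: Tensor, t: int) -> Tensor:
    """Slice time column ``t`` from a ``(batch x n x T)`` tensor."""
    out = Tensor(x.data[..., t], _parents=(x,))

    def bwd(g):
        full = np.zeros_like(x.data)
        full[..., t] = g
        x._accumulate(full)

    out._backward = bwd
    return out


def stack_time(cols: Sequence[Tensor]) -> Tensor:
    """Stack ``(batch x n)`` columns into ``(batch x n x T)``."""
    out = Tensor(np.stack([c.data for c in cols], axis=-1), _parents=tuple(cols))

    def bwd(g):
        for t, c in enumerate(cols):
            if c.requires_grad:
                c._accumulate(g[..., t])

    out._backward = bwd
    return out


def causal_conv(S: Tensor, taps: Tensor) -> Tensor:
    """Per-neuron causal convolution over time.

    ``S``: spike counts ``(batch x n x T)``; ``taps``: per-neuron kernel
    ``(n x K)``.  ``out[b, j, t] = sum_i S[b, j, t-i] * taps[j, i]`` with
    zero padding before t=0.
    """
    B, n, T = S.data.shape
    n2, K = taps.data.shape
    if n != n2:
        raise ValueError(f"neuron count mismatch: spikes {n}, taps {n2}")
    out_data = np.zeros_like(S.data)
    for i in range(K):
        if i == 0:
            out_data += S.data * taps.data[:, 0][None, :, None]
        else:
            out_data[..., i:] += S.data[..., :-i] * taps.data[:, i][None, :, None]
    out = Tensor(out_data, _parents=(S, taps))

    def bwd(g):
        if S.requires_grad:
            gS = np.zeros_like(S.data)
            for i in range(K):
                if i == 0:
                    gS += g * taps.data[:, 0][None, :, None]
                else:
                    gS[..., :-i] += g[..., i:] * taps.data[:, i][None, :, None]
            S._accumulate(gS)
        if taps.requires_grad:
            gt = np.zeros_like(taps.data)
            for i in range(K):
                if i == 0:
                    gt[:, 0] = (g * S.data).sum(axis=(0, 2))
                else:
                    gt[:, i] = (g[..., i:] * S.data[..., :-i]).sum(axis=(0, 2))
            taps._accumulate(gt)

    out._backward = bwd
    return out


def cross_entropy_mean(Z: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of logits ``Z (batch x classes)``.

    ``targets`` holds integer class indices.  Forward uses the shifted
    softmax for stability; backward is the classic ``(p - onehot)/B``.
    """
    targets = np.asarray(targets)
    B = Z.data.shape[0]
    shifted = Z.data - Z.data.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    p = expz / expz.sum(axis=1, keepdims=True)
    nll = -np.log(p[np.arange(B), targets] + 1e-300)
    out = Tensor(nll.mean(), _parents=(Z,))

    def bwd(g):
        dZ = p.copy()
        dZ[np.arange(B), targets] -= 1.0
        Z._accumulate(g * dZ / B)

    out._backward = bwd
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    """Plain (non-tape) stable softmax over the last axis."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)
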