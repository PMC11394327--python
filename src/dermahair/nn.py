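"""Minimal reverse-mode autodiff over numpy arrays, sized for desk-scale nets.

Supports exactly the operations the conditional U-Net denoiser needs:
2-D convolution (arbitrary odd kernel, 'same' padding), ReLU, 2x average
pooling, 2x nearest-neighbour upsampling, channel concatenation, dense
layers, per-sample/per-channel bias broadcast, and mean-squared-error loss.
Gradients are accumulated on leaf tensors by ``backward()`` over the
topologically sorted tape. Everything is float64; there is no GPU path —
the point is a dependency-free, finite-difference-checkable training stack.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


class Tensor:
    """Node in the computation tape wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: np.ndarray, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
                stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    assert a.shape == b.shape

    def bw(g: np.ndarray) -> None:
        _accum(a, g)
        _accum(b, g)

    return Tensor(a.data + b.data, parents=(a, b), backward=bw)


def add_broadcast(x: Tensor, t: Tensor) -> Tensor:
    """x (B,C,H,W) + t (B,C,1,1): per-sample per-channel shift."""
    assert x.data.ndim == 4 and t.data.shape == x.data.shape[:2] + (1, 1)

    def bw(g: np.ndarray) -> None:
        _accum(x, g)
        _accum(t, g.sum(axis=(2, 3), keepdims=True))

    return Tensor(x.data + t.data, parents=(x, t), backward=bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g: np.ndarray) -> None:
        _accum(x, g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bw)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis of (B,C,H,W) tensors."""
    ca = a.data.shape[1]

    def bw(g: np.ndarray) -> None:
        _accum(a, g[:, :ca])
        _accum(b, g[:, ca:])

    return Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b),
                  backward=bw)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = x.data.shape

    def bw(g: np.ndarray) -> None:
        _accum(x, g.reshape(orig))

    return Tensor(x.data.reshape(shape), parents=(x,), backward=bw)


# ---------------------------------------------------------------------------
# dense layer
# ---------------------------------------------------------------------------

def linear(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """x (B,D) @ W.T (D,K) + b (K,) -> (B,K)."""

    def bw(g: np.ndarray) -> None:
        _accum(x, g @ W.data)
        _accum(W, g.T @ x.data)
        _accum(b, g.sum(axis=0))

    return Tensor(x.data @ W.data.T + b.data, parents=(x, W, b), backward=bw)


# ---------------------------------------------------------------------------
# convolution (stride 1, 'same' padding for odd kernels)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((B, C, k, k, H, W), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + H, j:j + W]
    return cols.reshape(B, C * k * k, H * W)


def _col2im(dcols: np.ndarray, xshape: tuple[int, ...], k: int,
            pad: int) -> np.ndarray:
    B, C, H, W = xshape
    dcols = dcols.reshape(B, C, k, k, H, W)
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + H, j:j + W] += dcols[:, :, i, j]
    return dxp[:, :, pad:pad + H, pad:pad + W]


def conv2d(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 convolution; W is (Cout, Cin, k, k), b (Cout,)."""
    cout, cin, k, k2 = W.data.shape
    assert k == k2 and k % 2 == 1
    pad = k // 2
    B, C, H, Wd = x.data.shape
    assert C == cin
    cols = _im2col(x.data, k, pad)                     # (B, Cin*k*k, H*W)
    Wm = W.data.reshape(cout, cin * k * k)
    y = np.einsum("ok,bkp->bop", Wm, cols) + b.data[None, :, None]
    y = y.reshape(B, cout, H, Wd)

    def bw(g: np.ndarray) -> None:
        gm = g.reshape(B, cout, H * Wd)
        dW = np.einsum("bop,bkp->ok", gm, cols).reshape(W.data.shape)
        _accum(W, dW)
        _accum(b, gm.sum(axis=(0, 2)))
        dcols = np.einsum("ok,bop->bkp", Wm, gm)
        _accum(x, _col2im(dcols, x.data.shape, k, pad))

    return Tensor(y, parents=(x, W, b), backward=bw)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2 (even H, W required)."""
    B, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0
    y = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def bw(g: np.ndarray) -> None:
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
        _accum(x, gx)

    return Tensor(y, parents=(x,), backward=bw)


def upsample_nearest2(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling."""
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    B, C, H, W = x.data.shape

    def bw(g: np.ndarray) -> None:
        gx = g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5))
        _accum(x, gx)

    return Tensor(y, parents=(x,), backward=bw)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target."""
    target = np.asarray(target, dtype=np.float64)
    assert pred.data.shape == target.shape
    diff = pred.data - target
    n = diff.size

    def bw(g: np.ndarray) -> None:
        _accum(pred, (2.0 / n) * diff * g)

    return Tensor(np.array(np.mean(diff ** 2)), parents=(pred,), backward=bw)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.step_count = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        """Update ``params`` in place from ``grads``."""
        self.step_count += 1
        t = self.step_count
        for name, p in params.items():
            g = grads[name]
            if name not in self.m:
                self.m[name] = np.zeros_like(p)
                self.v[name] = np.zeros_like(p)
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / (1 - self.beta1 ** t)
            vhat = self.v[name] / (1 - self.beta2 ** t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {
            "lr": self.lr, "beta1": self.beta1, "beta2": self.beta2,
            "eps": self.eps, "step_count": self.step_count,
            "m": dict(self.m), "v": dict(self.v),
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "Adam":
        opt = cls(lr=state["lr"], beta1=state["beta1"], beta2=state["beta2"],
                  eps=state["eps"])
        opt.step_count = state["step_count"]
        opt.m = {k: np.array(v) for k, v in state["m"].items()}
        opt.v = {k: np.array(v) for k, v in state["v"].items()}
        return opt


def finite_difference_grads(loss_fn: Callable[[dict[str, np.ndarray]], float],
                            params: dict[str, np.ndarray],
                            h: float = 1e-6) -> dict[str, np.ndarray]:
    """Central-difference gradients of a scalar loss (test oracle, O(2P) evals)."""
    grads = {}
    for name, p in params.items():
        g = np.zeros_like(p)
        flat = p.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            lp = loss_fn(params)
            flat[i] = orig - h
            lm = loss_fn(params)
            flat[i] = orig
            gflat[i] = (lp - lm) / (2 * h)
        grads[name] = g
    return grads
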