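"""Layers and the Adam optimizer for the NumPy autodiff engine."""
from __future__ import annotations

import numpy as np


from .autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "Conv2d",
    "Dropout",
    "maxpool1d",
    "Adam",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in vars(self).values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch while loading state")
            p.data = a.astype(np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = Tensor(_kaiming(rng, (n_in, n_out), n_in), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """1-D convolution (cross-correlation), stride and symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        super().__init__()
        self.stride = stride
        self.padding = padding
        self.kernel = kernel
        self.w = Tensor(_kaiming(rng, (c_out, c_in, kernel), c_in * kernel), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        w, b, s, p, k = self.w, self.b, self.stride, self.padding, self.kernel
        xd = x.data
        if p:
            xd = np.pad(xd, ((0, 0), (0, 0), (p, p)))
        lout = (xd.shape[2] - k) // s + 1
        # shifted-slice accumulation beats an im2col einsum at these sizes
        out = np.empty((xd.shape[0], w.data.shape[0], lout))
        out[:] = b.data[:, None]
        for kk in range(k):
            out += np.matmul(w.data[:, :, kk], xd[:, :, kk : kk + s * lout : s])

        def bwd(g):
            if w.requires_grad:
                gw = np.empty_like(w.data)
                for kk in range(k):
                    gw[:, :, kk] = np.tensordot(
                        g, xd[:, :, kk : kk + s * lout : s], axes=([0, 2], [0, 2])
                    )
                w._accum(gw)
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2)))
            if x.requires_grad:
                gxp = np.zeros_like(xd)
                for kk in range(k):
                    gxp[:, :, kk : kk + s * lout : s] += np.matmul(w.data[:, :, kk].T, g)
                x._accum(gxp[:, :, p : gxp.shape[2] - p] if p else gxp)

        return Tensor._make(out, (x, w, b), bwd)


class Conv2d(Module):
    """2-D convolution, stride 1, symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 padding: int = 0, zero_init: bool = False):
        super().__init__()
        self.padding = padding
        self.kernel = kernel
        init = (np.zeros((c_out, c_in, kernel, kernel)) if zero_init
                else _kaiming(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel))
        self.w = Tensor(init, requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        w, b, p, k = self.w, self.b, self.padding, self.kernel
        xd = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
        hout = xd.shape[2] - k + 1
        wout = xd.shape[3] - k + 1
        out = np.empty((xd.shape[0], w.data.shape[0], hout, wout))
        out[:] = b.data[None, :, None, None]
        for i in range(k):
            for j in range(k):
                out += np.einsum(
                    "bchw,oc->bohw", xd[:, :, i : i + hout, j : j + wout],
                    w.data[:, :, i, j], optimize=True,
                )

        def bwd(g):
            if w.requires_grad:
                gw = np.empty_like(w.data)
                for i in range(k):
                    for j in range(k):
                        gw[:, :, i, j] = np.tensordot(
                            g, xd[:, :, i : i + hout, j : j + wout],
                            axes=([0, 2, 3], [0, 2, 3]),
                        )
                w._accum(gw)
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxp = np.zeros_like(xd)
                for i in range(k):
                    for j in range(k):
                        gxp[:, :, i : i + hout, j : j + wout] += np.einsum(
                            "bohw,oc->bchw", g, w.data[:, :, i, j], optimize=True
                        )
                if p:
                    gxp = gxp[:, :, p:-p, p:-p]
                x._accum(gxp)

        return Tensor._make(out, (x, w, b), bwd)


def maxpool1d(x: Tensor, kernel: int = 2) -> Tensor:
    """Non-overlapping max pooling along the last axis (truncates remainder)."""
    b, c, l = x.data.shape
    lout = l // kernel
    view = x.data[:, :, : lout * kernel].reshape(b, c, lout, kernel)
    idx = np.argmax(view, axis=3)
    out = np.max(view, axis=3)

    def bwd(g):
        if not x.requires_grad:
            return
        grad = np.zeros((b, c, lout, kernel))
        np.put_along_axis(grad, idx[..., None], g[..., None], axis=3)
        full = np.zeros_like(x.data)
        full[:, :, : lout * kernel] = grad.reshape(b, c, lout * kernel)
        x._accum(full)

    return Tensor._make(out, (x,), bwd)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
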