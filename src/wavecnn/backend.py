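"""Numpy execution backend for the layer graph.

Binds an :class:`~wavecnn.architecture.ArchitectureGraph` to an executable
model with forward and reverse-mode passes written directly in numpy
(im2col/col2im convolutions, batch normalization with moving statistics,
inverted dropout, softmax cross-entropy) and an Adam optimizer.  Everything
is seeded, single-threaded deterministic, and float32 by default.

The wavelet taps are evaluated with the same filter bank as
:mod:`wavecnn.haar` and are treated as constants of the input: no gradient
flows through them because nothing trainable sits upstream.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .architecture import ArchitectureGraph, _pool_sum, _same_pad, forward_shapes
from .exceptions import AuditError, ShapeError
from .haar import HaarFilterBank


def batched_dwt_level(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """One Haar level of a (N, H, W, C) batch -> (N, H/2, W/2, 4C)."""
    n, h, w, c = x.shape
    blocks = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = np.einsum("niajbc,kab->nijck", blocks, kernels, optimize=True)
    return out.reshape(n, h // 2, w // 2, 4 * c)


def batched_dwt_pyramid(x: np.ndarray, levels: int, bank: HaarFilterBank) -> list[np.ndarray]:
    kernels = bank.stacked().astype(x.dtype)
    stacks = []
    current = x
    for _ in range(levels):
        stack = batched_dwt_level(current, kernels)
        stacks.append(stack)
        current = stack[:, :, :, 0::4]
    return stacks


class _Layer:
    trainable: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.trainable = []
        self.grads = []
        self.non_trainable: list[np.ndarray] = []

    def forward(self, x, train):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class _Conv2D(_Layer):
    def __init__(self, c_in, c_out, kernel, stride, rng, dtype):
        super().__init__()
        self.k, self.stride = kernel, stride
        fan_in = kernel * kernel * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (kernel, kernel, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.trainable = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _pads(self, h, w):
        oh, pt, pb = _same_pad(h, self.k, self.stride)
        ow, pl, pr = _same_pad(w, self.k, self.stride)
        return oh, ow, (pt, pb), (pl, pr)

    def forward(self, x, train):
        n, h, w, c = x.shape
        oh, ow, ph, pw = self._pads(h, w)
        xp = np.pad(x, ((0, 0), ph, pw, (0, 0)))
        view = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        view = view[:, :: self.stride, :: self.stride]  # (n, oh, ow, c, k, k)
        cols = np.ascontiguousarray(view.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * oh * ow, self.k * self.k * c
        )
        y = cols @ self.W.reshape(-1, self.W.shape[-1]) + self.b
        if train:
            self._cache = (cols, x.shape, (oh, ow, ph, pw))
        return y.reshape(n, oh, ow, -1)

    def backward(self, dy):
        cols, xshape, (oh, ow, ph, pw) = self._cache
        n, h, w, c = xshape
        c_out = dy.shape[-1]
        dyf = dy.reshape(-1, c_out)
        self.grads[0][...] = (cols.T @ dyf).reshape(self.W.shape)
        self.grads[1][...] = dyf.sum(axis=0)
        dcols = (dyf @ self.W.reshape(-1, c_out).T).reshape(n, oh, ow, self.k, self.k, c)
        dxp = np.zeros((n, h + sum(ph), w + sum(pw), c), dtype=dy.dtype)
        s = self.stride
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, di : di + oh * s : s, dj : dj + ow * s : s, :] += dcols[:, :, :, di, dj, :]
        self._cache = None
        return dxp[:, ph[0] : h + ph[0], pw[0] : w + pw[0], :]


class _BatchNorm(_Layer):
    def __init__(self, channels, rng, dtype, momentum=0.9, eps=1e-3):
        super().__init__()
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.moving_mean = np.zeros(channels, dtype=dtype)
        self.moving_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self.trainable = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.non_trainable = [self.moving_mean, self.moving_var]

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.moving_mean *= self.momentum
            self.moving_mean += (1 - self.momentum) * mu
            self.moving_var *= self.momentum
            self.moving_var += (1 - self.momentum) * var
        else:
            mu, var = self.moving_mean, self.moving_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv, axes)
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        xhat, inv, axes = self._cache
        m = np.prod([dy.shape[a] for a in axes])
        self.grads[0][...] = (dy * xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
        ) * inv
        self._cache = None
        return dx.astype(dy.dtype, copy=False)


class _ReLU(_Layer):
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class _Dense(_Layer):
    def __init__(self, n_in, n_out, rng, dtype):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.trainable = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx


class _Dropout(_Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class _AvgPool(_Layer):
    def __init__(self, window, stride, padding):
        super().__init__()
        self.window, self.stride, self.padding = window, stride, padding

    def forward(self, x, train):
        out, counts = _pool_sum(x, self.window, self.stride, self.padding)
        if train:
            self._cache = (x.shape, counts)
        return out / counts[None, :, :, None].astype(x.dtype)

    def backward(self, dy):
        xshape, counts = self._cache
        n, h, w, c = xshape
        g = dy / counts[None, :, :, None].astype(dy.dtype)
        oh, ow = g.shape[1:3]
        if self.padding == "same":
            _, pt, pb = _same_pad(h, self.window, self.stride)
            _, pl, pr = _same_pad(w, self.window, self.stride)
        else:
            pt = pb = pl = pr = 0
        dxp = np.zeros((n, h + pt + pb, w + pl + pr, c), dtype=dy.dtype)
        s = self.stride
        for di in range(self.window):
            for dj in range(self.window):
                dxp[:, di : di + oh * s : s, dj : dj + ow * s : s, :] += g
        self._cache = None
        return dxp[:, pt : h + pt, pl : w + pl, :]


class _Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Concat(_Layer):
    def forward(self, xs, train):
        self._splits = np.cumsum([x.shape[-1] for x in xs])[:-1]
        for a, b in zip(xs[:-1], xs[1:]):
            if a.shape[1:3] != b.shape[1:3]:
                raise ShapeError(f"concat spatial mismatch: {a.shape} vs {b.shape}")
        return np.concatenate(xs, axis=-1)

    def backward(self, dy):
        return np.split(dy, self._splits, axis=-1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)


_SGD_KINDS = {"input", "wavelet"}


class NumpyModel:
    """Executable realization of an ArchitectureGraph.

    Parameters are initialized from ``seed`` (He-normal weights, unit-scale
    batchnorm); dropout noise uses an independent stream split from the same
    seed, so two models built with the same seed produce identical outputs
    given identical call sequences.
    """

    def __init__(
        self,
        graph: ArchitectureGraph,
        seed: int = 0,
        dtype=np.float32,
        wavelet_mode: str = "orthonormal",
        bn_momentum: float = 0.9,
    ):
        self.graph = graph
        self.dtype = dtype
        self.bank = HaarFilterBank(wavelet_mode)
        self.shapes = forward_shapes(graph)
        ss = np.random.SeedSequence(seed)
        init_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        self._layers: dict[str, _Layer | None] = {}
        self._max_level = 0
        for spec in graph.layers:
            try:
                self._layers[spec.name] = self._build_layer(spec, init_rng, drop_rng, bn_momentum)
            except Exception as exc:  # noqa: BLE001 - re-raise with layer context
                raise AuditError(f"cannot instantiate layer {spec.name!r}: {exc}") from exc

    def _build_layer(self, spec, init_rng, drop_rng, bn_momentum):
        kind = spec.kind
        if kind in _SGD_KINDS:
            if kind == "wavelet":
                self._max_level = max(self._max_level, spec.hyper["level"])
            return None
        if kind == "conv":
            c_in = self.shapes[spec.inputs[0]][2]
            return _Conv2D(
                c_in, spec.hyper["filters"], spec.hyper["kernel"], spec.hyper["stride"],
                init_rng, self.dtype,
            )
        if kind == "batchnorm":
            return _BatchNorm(
                self.shapes[spec.inputs[0]][-1], init_rng, self.dtype, momentum=bn_momentum
            )
        if kind == "relu":
            return _ReLU()
        if kind == "dense":
            return _Dense(self.shapes[spec.inputs[0]][0], spec.hyper["units"], init_rng, self.dtype)
        if kind == "dropout":
            return _Dropout(spec.hyper["rate"], drop_rng)
        if kind == "avgpool":
            return _AvgPool(spec.hyper["window"], spec.hyper["stride"], spec.hyper["padding"])
        if kind == "flatten":
            return _Flatten()
        if kind == "concat":
            return _Concat()
        raise AuditError(f"unsupported layer kind {kind!r}")

    # ------------------------------------------------------------------ #

    def forward(self, x, train: bool = False, return_all: bool = False):
        """Logits of a (N, H, W, C) batch (pre-softmax)."""
        x = np.asarray(x, dtype=self.dtype)
        outputs: dict[str, np.ndarray] = {}
        pyramid = batched_dwt_pyramid(x, self._max_level, self.bank) if self._max_level else []
        last = None
        for spec in self.graph.layers:
            if spec.kind == "input":
                out = x
            elif spec.kind == "wavelet":
                out = pyramid[spec.hyper["level"] - 1]
            elif spec.kind == "concat":
                out = self._layers[spec.name].forward(
                    [outputs[n] for n in spec.inputs], train
                )
            else:
                out = self._layers[spec.name].forward(outputs[spec.inputs[0]], train)
            outputs[spec.name] = out
            last = out
        if return_all:
            return last, outputs
        return last

    def predict_proba(self, x, batch_size: int = 8) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        probs = [
            softmax(self.forward(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(probs, axis=0)

    def _backward(self, dlast):
        grad: dict[str, np.ndarray] = {self.graph.layers[-1].name: dlast}
        for spec in reversed(self.graph.layers):
            if spec.name not in grad or spec.kind in _SGD_KINDS:
                continue
            dy = grad.pop(spec.name)
            dx = self._layers[spec.name].backward(dy)
            if spec.kind == "concat":
                parts = dx
            else:
                parts = [dx]
            for inp, part in zip(spec.inputs, parts):
                if inp in grad:
                    grad[inp] = grad[inp] + part
                else:
                    grad[inp] = part

    def train_step(self, x, y, optimizer: Adam):
        """One optimizer step on a batch; returns (mean CE loss, n correct)."""
        logits = self.forward(x, train=True)
        p = softmax(logits.astype(np.float64))
        n = len(y)
        eps = 1e-12
        loss = -np.log(p[np.arange(n), y] + eps).mean()
        correct = int((p.argmax(axis=1) == y).sum())
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        self._backward((dlogits / n).astype(self.dtype))
        optimizer.step(self.gradients())
        return float(loss), correct

    # ------------------------------------------------------------------ #

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers.values():
            if layer is not None:
                out.extend(layer.trainable)
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers.values():
            if layer is not None:
                out.extend(layer.grads)
        return out

    def parameter_counts(self) -> tuple[int, int]:
        """(trainable, non_trainable) as counted by the backend itself."""
        t = sum(p.size for p in self.parameters())
        n = sum(
            p.size
            for layer in self._layers.values()
            if layer is not None
            for p in layer.non_trainable
        )
        return t, n

    def get_state(self) -> dict[str, np.ndarray]:
        state = {}
        for name, layer in self._layers.items():
            if layer is None:
                continue
            for i, p in enumerate(layer.trainable):
                state[f"{name}/t{i}"] = p.copy()
            for i, p in enumerate(layer.non_trainable):
                state[f"{name}/n{i}"] = p.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self._layers.items():
            if layer is None:
                continue
            for i, p in enumerate(layer.trainable):
                p[...] = state[f"{name}/t{i}"]
            for i, p in enumerate(layer.non_trainable):
                p[...] = state[f"{name}/n{i}"]


def instantiate_model(graph: ArchitectureGraph, seed: int = 0, **kwargs) -> NumpyModel:
    """Bind a layer graph to the numpy backend with seeded initialization."""
    return NumpyModel(graph, seed=seed, **kwargs)
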