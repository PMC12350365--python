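"""A compact feed-forward/convolutional network engine on numpy.

Implements exactly the layer vocabulary the yield models need — 1D/2D valid
convolutions, average pooling, dense layers, categorical embeddings, ELU
activations, L1 weight regularization — with reverse-mode gradients and an
Adam optimizer. Shapes follow the channels-last convention: 1D inputs are
(n, length, channels), 2D inputs (n, height, width, channels).

The engine is deliberately small: stride-1 valid convolutions only, full
determinism under a seeded ``numpy.random.Generator``, and no GPU paths.
Gradient correctness is pinned by finite-difference tests in the suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def elu(x, alpha: float = 1.0):
    """Exponential linear unit: x for x > 0, alpha*(exp(x) - 1) otherwise."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))
    return out if out.ndim else float(out)


def _elu_grad(x, alpha: float):
    return np.where(x > 0, 1.0, alpha * np.exp(np.minimum(x, 0.0)))


class Layer:
    """Base layer: params/grads lists plus forward/backward."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class _Activated(Layer):
    """Mixin handling the post-affine activation."""

    def __init__(self, activation: str, alpha: float) -> None:
        super().__init__()
        if activation not in ("elu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.alpha = alpha
        self._z: np.ndarray | None = None

    def _act(self, z: np.ndarray) -> np.ndarray:
        self._z = z
        return elu(z, self.alpha) if self.activation == "elu" else z

    def _act_grad(self, grad: np.ndarray) -> np.ndarray:
        if self.activation == "elu":
            return grad * _elu_grad(self._z, self.alpha)
        return grad


class Dense(_Activated):
    def __init__(self, n_in: int, n_out: int, activation: str = "elu",
                 alpha: float = 1.0, l1: float = 0.0, rng: np.random.Generator | None = None):
        super().__init__(activation, alpha)
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.l1 = l1
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return self._act(x @ self.w + self.b)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self._act_grad(grad)
        self.grads[0][...] = self._x.T @ grad
        if self.l1:
            self.grads[0] += self.l1 * np.sign(self.w)
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T

    def l1_penalty(self) -> float:
        return float(self.l1 * np.abs(self.w).sum()) if self.l1 else 0.0


class Conv1D(_Activated):
    """Stride-1 valid 1D convolution over (n, length, channels)."""

    def __init__(self, c_in: int, filters: int, kernel: int, activation: str = "elu",
                 alpha: float = 1.0, rng: np.random.Generator | None = None):
        super().__init__(activation, alpha)
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.w = rng.normal(0, scale, size=(kernel * c_in, filters))
        self.b = np.zeros(filters)
        self.c_in, self.filters = c_in, filters
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, L, c = x.shape
        if L < self.kernel:
            raise ValueError(f"input length {L} smaller than kernel {self.kernel}")
        # (n, Lout, c, k) -> (n, Lout, k*c)
        win = sliding_window_view(x, self.kernel, axis=1)
        self._patches = win.transpose(0, 1, 3, 2).reshape(n, L - self.kernel + 1, -1)
        self._in_shape = x.shape
        return self._act(self._patches @ self.w + self.b)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self._act_grad(grad)
        n, Lout, _ = grad.shape
        flat_p = self._patches.reshape(-1, self.w.shape[0])
        self.grads[0][...] = flat_p.T @ grad.reshape(-1, self.filters)
        self.grads[1][...] = grad.sum(axis=(0, 1))
        dpatch = (grad @ self.w.T).reshape(n, Lout, self.kernel, self.c_in)
        dx = np.zeros(self._in_shape)
        for i in range(self.kernel):
            dx[:, i:i + Lout, :] += dpatch[:, :, i, :]
        return dx


class Conv2D(_Activated):
    """Stride-1 valid 2D convolution over (n, height, width, channels)."""

    def __init__(self, c_in: int, filters: int, kernel: tuple[int, int], activation: str = "elu",
                 alpha: float = 1.0, rng: np.random.Generator | None = None):
        super().__init__(activation, alpha)
        rng = rng or np.random.default_rng(0)
        self.kh, self.kw = kernel
        scale = np.sqrt(2.0 / (self.kh * self.kw * c_in))
        self.w = rng.normal(0, scale, size=(self.kh * self.kw * c_in, filters))
        self.b = np.zeros(filters)
        self.c_in, self.filters = c_in, filters
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, H, W, c = x.shape
        if H < self.kh or W < self.kw:
            raise ValueError(f"input {H}x{W} smaller than kernel {self.kh}x{self.kw}")
        win = sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        # (n, Ho, Wo, c, kh, kw) -> (n, Ho, Wo, kh*kw*c)
        self._Ho, self._Wo = H - self.kh + 1, W - self.kw + 1
        self._patches = win.transpose(0, 1, 2, 4, 5, 3).reshape(n, self._Ho, self._Wo, -1)
        self._in_shape = x.shape
        return self._act(self._patches @ self.w + self.b)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self._act_grad(grad)
        n = grad.shape[0]
        flat_p = self._patches.reshape(-1, self.w.shape[0])
        self.grads[0][...] = flat_p.T @ grad.reshape(-1, self.filters)
        self.grads[1][...] = grad.sum(axis=(0, 1, 2))
        dpatch = (grad @ self.w.T).reshape(n, self._Ho, self._Wo, self.kh, self.kw, self.c_in)
        dx = np.zeros(self._in_shape)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i:i + self._Ho, j:j + self._Wo, :] += dpatch[:, :, :, i, j, :]
        return dx


class AvgPool1D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, L, c = x.shape
        self._in_shape = x.shape
        Lp = (L // self.pool) * self.pool
        self._Lp = Lp
        return x[:, :Lp, :].reshape(n, Lp // self.pool, self.pool, c).mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape)
        expanded = np.repeat(grad / self.pool, self.pool, axis=1)
        dx[:, :self._Lp, :] = expanded
        return dx


class AvgPool2D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, H, W, c = x.shape
        self._in_shape = x.shape
        p = self.pool
        Hp, Wp = (H // p) * p, (W // p) * p
        self._Hp, self._Wp = Hp, Wp
        xr = x[:, :Hp, :Wp, :].reshape(n, Hp // p, p, Wp // p, p, c)
        return xr.mean(axis=(2, 4))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p = self.pool
        dx = np.zeros(self._in_shape)
        g = grad / (p * p)
        g = np.repeat(np.repeat(g, p, axis=1), p, axis=2)
        dx[:, :self._Hp, :self._Wp, :] = g
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class EmbedConcat(Layer):
    """Embedding layers for integer-coded categoricals, concatenated with numerics.

    Input is (n, n_cat + n_num): the first ``n_cat`` columns hold integer
    category codes, the rest numeric features. Output is the flat
    concatenation of all embedding vectors and the numeric block. Input
    gradients are not propagated (the inputs are leaves); embedding tables
    are trained.
    """

    def __init__(self, cardinalities: list[int], n_numeric: int,
                 dims: list[int] | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if dims is None:
            dims = [min(8, int(np.ceil(c / 2))) for c in cardinalities]
        self.cardinalities = cardinalities
        self.dims = dims
        self.n_numeric = n_numeric
        self.tables = [rng.normal(0, 0.1, size=(c, d)) for c, d in zip(cardinalities, dims)]
        self.params = list(self.tables)
        self.grads = [np.zeros_like(t) for t in self.tables]
        self.out_width = sum(dims) + n_numeric

    def forward(self, x: np.ndarray) -> np.ndarray:
        n_cat = len(self.cardinalities)
        self._codes = x[:, :n_cat].astype(int)
        numeric = x[:, n_cat:]
        parts = [self.tables[i][self._codes[:, i]] for i in range(n_cat)]
        parts.append(numeric)
        return np.concatenate(parts, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        offset = 0
        for i, d in enumerate(self.dims):
            self.grads[i][...] = 0.0
            np.add.at(self.grads[i], self._codes[:, i], grad[:, offset:offset + d])
            offset += d
        return np.zeros((grad.shape[0], len(self.cardinalities) + self.n_numeric))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def all_params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                pairs += layer.all_params()
            else:
                pairs += list(zip(layer.params, layer.grads))
        return pairs

    def l1_penalty(self) -> float:
        total = 0.0
        for layer in self.layers:
            if isinstance(layer, (Sequential, Dense)):
                total += layer.l1_penalty() if hasattr(layer, "l1_penalty") else 0.0
        return total


class Adam:
    """Adam optimizer over (param, grad) pairs."""

    def __init__(self, pairs: list[tuple[np.ndarray, np.ndarray]], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = pairs
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in pairs]
        self.v = [np.zeros_like(p) for p, _ in pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MultiBranch(Layer):
    """Parallel branches whose outputs are concatenated and fed to a head.

    ``forward`` takes a list of arrays, one per branch. Branches that are
    themselves ``MultiBranch`` (nested parallel blocks) receive a list.
    """

    def __init__(self, branches: list[tuple[str, Layer]], head: Sequential):
        super().__init__()
        self.branches = branches
        self.head = head

    def forward(self, inputs: list) -> np.ndarray:
        self._outs = [branch.forward(x) for (_, branch), x in zip(self.branches, inputs)]
        self._widths = [o.shape[1] for o in self._outs]
        return self.head.forward(np.concatenate(self._outs, axis=1))

    def backward(self, grad: np.ndarray) -> list:
        g = self.head.backward(grad)
        grads_in, offset = [], 0
        for (_, branch), w in zip(self.branches, self._widths):
            grads_in.append(branch.backward(g[:, offset:offset + w]))
            offset += w
        return grads_in

    def all_params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = []
        for _, branch in self.branches:
            if hasattr(branch, "all_params"):
                pairs += branch.all_params()
            else:
                pairs += list(zip(branch.params, branch.grads))
        pairs += self.head.all_params()
        return pairs

    def l1_penalty(self) -> float:
        total = sum(b.l1_penalty() for _, b in self.branches if hasattr(b, "l1_penalty"))
        return total + self.head.l1_penalty()
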