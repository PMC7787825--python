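"""Minimal CNN engine: layers, backprop and Adam, in float32 numpy.

Just enough machinery for the fusion classifier: stride-1 2-D convolutions
(``same``/``valid``), 2x2 max pooling with floor semantics, dense layers, a
parametric ELU whose negative-branch scale ``lambda`` is learned by
backpropagation, softmax cross-entropy, and Adam.  Convolutions use im2col
so the heavy lifting is a single BLAS matmul per layer.

Everything is deterministic given the ``numpy.random.Generator`` used for
initialization and batching.
"""

from __future__ import annotations

import ctypes

import numpy as np

DTYPE = np.float32

# Each training step allocates and frees ~100-200 MB im2col scratch blocks;
# above glibc's default mmap threshold those round-trip through mmap/munmap
# (page faults on every touch), which roughly doubles step time.  Raising
# the threshold lets malloc recycle the equal-sized blocks from its free
# lists.  No-op on non-glibc platforms.
try:  # pragma: no cover - platform-dependent
    _libc = ctypes.CDLL("libc.so.6", use_errno=True)
    _libc.mallopt(ctypes.c_int(-3), ctypes.c_int(1 << 30))  # M_MMAP_THRESHOLD
except (OSError, AttributeError):
    pass


# ------------------------------------------------------------ activations


class PELU:
    """Exponential linear unit with (optionally learnable) negative scale.

    g(x) = x for x > 0, lambda * (exp(x) - 1) otherwise; continuous at 0.
    """

    def __init__(self, lam: float = 1.0, trainable: bool = True) -> None:
        self.lam = np.array(lam, dtype=DTYPE)
        self.trainable = trainable
        self.grad_lam = np.zeros_like(self.lam)
        self._z: np.ndarray | None = None

    def forward(self, z: np.ndarray) -> np.ndarray:
        # clip before expm1: np.where evaluates both branches
        self._pos = z > 0
        self._em1 = np.expm1(np.minimum(z, 0))
        return np.where(self._pos, z, self.lam * self._em1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        pos, em1 = self._pos, self._em1
        if self.trainable:
            self.grad_lam = np.array(np.sum(np.where(pos, 0.0, g * em1)), dtype=DTYPE)
        else:
            self.grad_lam = np.zeros_like(self.lam)
        # d/dz = lam * exp(z) = lam * (expm1(z) + 1) on the negative branch
        dz = np.where(pos, g, g * (self.lam * (em1 + 1.0))).astype(DTYPE)
        # flush saturated-branch underflow: subnormal gradients are numerical
        # noise but slow BLAS down by orders of magnitude
        dz[np.abs(dz) < 1e-30] = 0.0
        return dz

    def param_grads(self):
        return [(self.lam, lambda: self.grad_lam)] if self.trainable else []


def elu(x, lam: float = 1.0):
    """Reference scalar/array ELU (inference form of :class:`PELU`)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, x, lam * np.expm1(x))
    return out.item() if out.ndim == 0 else out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ----------------------------------------------------------------- layers


class Layer:
    def build(self, in_shape: tuple[int, ...], rng: np.random.Generator) -> tuple[int, ...]:
        raise NotImplementedError

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_grads(self):
        return []


class Conv2D(Layer):
    """Stride-1 2-D convolution over (N, H, W, C) input, via im2col.

    ``same`` padding pads (k-1)//2 before and the remainder after, so the
    output spatial size equals the input for both odd and even kernels.
    """

    def __init__(self, kh: int, kw: int, n_kernels: int, padding: str = "valid",
                 activation: str | None = "elu", fixed_lambda: bool = False) -> None:
        if kh < 1 or kw < 1 or n_kernels < 1:
            raise ValueError("kernel dims and count must be positive")
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.kh, self.kw, self.n_kernels, self.padding = kh, kw, n_kernels, padding
        self.act = PELU(trainable=not fixed_lambda) if activation == "elu" else None
        self.w = self.b = self.gw = self.gb = None
        self._cols = None
        self._in_shape = None
        #: set False for a branch's first layer: nothing consumes its dx
        self.need_input_grad = True

    def build(self, in_shape, rng):
        h, w, c = in_shape
        if self.padding == "valid" and (h < self.kh or w < self.kw):
            raise ValueError(f"input {in_shape} smaller than kernel ({self.kh},{self.kw})")
        fan_in = self.kh * self.kw * c
        self.w = (rng.standard_normal((fan_in, self.n_kernels)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(self.n_kernels, dtype=DTYPE)
        self._in_shape = in_shape
        if self.padding == "same":
            return (h, w, self.n_kernels)
        return (h - self.kh + 1, w - self.kw + 1, self.n_kernels)

    def _pad(self) -> tuple[tuple[int, int], tuple[int, int]]:
        if self.padding == "valid":
            return (0, 0), (0, 0)
        ph, pw = self.kh - 1, self.kw - 1
        return (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)

    def forward(self, x):
        (pt, pb), (pl, pr) = self._pad()
        if pt or pb or pl or pr:
            x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        n, h, w, c = x.shape
        ho, wo = h - self.kh + 1, w - self.kw + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        # (N, Ho, Wo, C, kh, kw) flattened in that order; weight rows use the
        # same (C, kh, kw) layout, so no transpose copy is needed
        cols = win.reshape(n * ho * wo, c * self.kh * self.kw)
        self._cols = cols
        self._padded_shape = (n, h, w, c)
        z = (cols @ self.w + self.b).reshape(n, ho, wo, self.n_kernels)
        return self.act.forward(z) if self.act else z

    def backward(self, g):
        if self.act:
            g = self.act.backward(g)
        n, ho, wo, _ = g.shape
        gf = g.reshape(n * ho * wo, self.n_kernels)
        self.gw = self._cols.T @ gf
        self.gb = gf.sum(axis=0)
        self._cols = None
        if not self.need_input_grad:
            return None
        nh, hh, ww, cc = self._padded_shape
        # one contiguous rearrangement, then contiguous scatter-adds
        dcols = np.ascontiguousarray(
            (gf @ self.w.T).reshape(n, ho, wo, cc, self.kh, self.kw).transpose(0, 1, 2, 4, 5, 3)
        )
        dx = np.zeros((nh, hh, ww, cc), dtype=DTYPE)
        for u in range(self.kh):
            for v in range(self.kw):
                dx[:, u : u + ho, v : v + wo, :] += dcols[:, :, :, u, v, :]
        (pt, pb), (pl, pr) = self._pad()
        return dx[:, pt : hh - pb, pl : ww - pr, :]

    def param_grads(self):
        out = [(self.w, lambda: self.gw), (self.b, lambda: self.gb)]
        if self.act:
            out += self.act.param_grads()
        return out


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; incomplete border windows are dropped."""

    def __init__(self, size: int = 2) -> None:
        self.size = size
        self._argmax = None

    def build(self, in_shape, rng):
        h, w, c = in_shape
        if h < self.size or w < self.size:
            raise ValueError(f"input {in_shape} smaller than pool window")
        return (h // self.size, w // self.size, c)

    def forward(self, x):
        s = self.size
        n, h, w, c = x.shape
        ho, wo = h // s, w // s
        self._in_shape = x.shape
        xc = x[:, : ho * s, : wo * s, :]
        patches = xc.reshape(n, ho, s, wo, s, c).transpose(0, 1, 3, 2, 4, 5).reshape(
            n, ho, wo, s * s, c
        )
        self._argmax = patches.argmax(axis=3)
        return patches.max(axis=3)

    def backward(self, g):
        s = self.size
        n, ho, wo, c = g.shape
        dpatch = np.zeros((n, ho, wo, s * s, c), dtype=DTYPE)
        np.put_along_axis(dpatch, self._argmax[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        dxc = dpatch.reshape(n, ho, wo, s, s, c).transpose(0, 1, 3, 2, 4, 5).reshape(
            n, ho * s, wo * s, c
        )
        _, h, w, _ = self._in_shape
        if (h, w) != (ho * s, wo * s):
            dx = np.zeros(self._in_shape, dtype=DTYPE)
            dx[:, : ho * s, : wo * s, :] = dxc
            return dx
        return dxc


def maxpool(window: np.ndarray) -> float:
    """Maximum of one pooling window (reference form)."""
    window = np.asarray(window)
    if window.size == 0:
        raise ValueError("empty pooling window")
    return float(window.max())


class Flatten(Layer):
    def build(self, in_shape, rng):
        return (int(np.prod(in_shape)),)

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, units: int, activation: str | None = "elu",
                 fixed_lambda: bool = False) -> None:
        if units < 1:
            raise ValueError("units must be positive")
        self.units = units
        self.act = PELU(trainable=not fixed_lambda) if activation == "elu" else None
        self.w = self.b = self.gw = self.gb = None

    def build(self, in_shape, rng):
        (fan_in,) = in_shape
        self.w = (rng.standard_normal((fan_in, self.units)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(self.units, dtype=DTYPE)
        return (self.units,)

    def forward(self, x):
        self._x = x
        z = x @ self.w + self.b
        return self.act.forward(z) if self.act else z

    def backward(self, g):
        if self.act:
            g = self.act.backward(g)
        self.gw = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.w.T

    def param_grads(self):
        out = [(self.w, lambda: self.gw), (self.b, lambda: self.gb)]
        if self.act:
            out += self.act.param_grads()
        return out


# ------------------------------------------------------------------ model


class MultiBranchNet:
    """Named branches whose outputs are concatenated into a head.

    ``forward`` takes a dict of per-branch inputs (N, H, W, 1); the head
    produces logits; :meth:`predict_proba` applies softmax.
    """

    def __init__(self, branches: dict[str, list[Layer]], head: list[Layer]) -> None:
        self.branches = branches
        self.head = head
        self._branch_dims: dict[str, int] = {}
        self.built = False

    def build(self, input_shapes: dict[str, tuple[int, ...]], rng: np.random.Generator) -> None:
        concat = 0
        for name, layers in self.branches.items():
            shape = input_shapes[name]
            for layer in layers:
                shape = layer.build(shape, rng)
            if isinstance(layers[0], Conv2D):
                layers[0].need_input_grad = False
            (dim,) = shape
            self._branch_dims[name] = dim
            concat += dim
        shape = (concat,)
        for layer in self.head:
            shape = layer.build(shape, rng)
        self.out_dim = shape[0]
        self.built = True

    @property
    def concat_dim(self) -> int:
        return sum(self._branch_dims.values())

    def forward(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        outs = []
        for name, layers in self.branches.items():
            x = inputs[name].astype(DTYPE, copy=False)
            for layer in layers:
                x = layer.forward(x)
            outs.append(x)
        x = np.concatenate(outs, axis=1)
        for layer in self.head:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.head):
            g = layer.backward(g)
        ofs = 0
        for name, layers in self.branches.items():
            d = self._branch_dims[name]
            gb = g[:, ofs : ofs + d]
            ofs += d
            for layer in reversed(layers):
                gb = layer.backward(gb)

    def predict_proba(self, inputs: dict[str, np.ndarray], batch_size: int = 64) -> np.ndarray:
        n = next(iter(inputs.values())).shape[0]
        out = []
        for i in range(0, n, batch_size):
            batch = {k: v[i : i + batch_size] for k, v in inputs.items()}
            out.append(softmax(self.forward(batch)))
        return np.concatenate(out, axis=0)

    def param_grads(self):
        out = []
        for layers in list(self.branches.values()) + [self.head]:
            for layer in layers:
                out += layer.param_grads()
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.param_grads()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.param_grads(), weights):
            p[...] = w

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.param_grads()))


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12))))
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, (g / n).astype(DTYPE)


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, param_grads) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p, _ in param_grads]
            self._v = [np.zeros_like(p) for p, _ in param_grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, grad_fn) in enumerate(param_grads):
            g = grad_fn()
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1**self.t)
            vhat = self._v[i] / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
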