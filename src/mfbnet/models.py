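"""Fusion classifier architectures for multilayer networks + FBCSP images.

The classifier has up to three convolutional branches sharing one softmax
head:

* two identical "MFCNN" branches, one per brain-network layer (mu, beta),
  each consuming a C x C sparsified PLV adjacency matrix; ``same`` padding,
  so the spatial extent survives until pooling;
* one "FBCSP" branch consuming the 43 x F feature image with wide ``valid``
  kernels (height 3: each kernel fuses three adjacent filter-bank bands).

Each branch flattens into a 64-unit dense layer; branch outputs are
concatenated and a dense softmax layer yields the 4-class posterior.  All
convolution/dense activations are parametric ELUs whose negative-branch
scale is learned.

Architectures are declared as :class:`LayerSpec` lists so that output shapes
can be traced arithmetically without building a network, and the ablation
variants (A-E) are edits of the declaration, not separate code paths:

==========  ==========================================================
variant     edit
==========  ==========================================================
``full``    both MFCNN branches + FBCSP branch
``A``       mu-band MFCNN branch removed
``B``       beta-band MFCNN branch removed
``C``       two extra convs after the 2nd/3rd convs of the mu branch
``D``       two extra convs after the 2nd/3rd convs of the beta branch
``E``       FBCSP branch's first kernel shrunk to 2 x 32
==========  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mfbnet._nn import (
    Adam,
    Conv2D,
    Dense,
    Flatten,
    Layer,
    MaxPool2D,
    MultiBranchNet,
    cross_entropy_grad,
    elu,
    maxpool,
    softmax,
)

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "TrainConfig",
    "VARIANTS",
    "mfcnn_branch_spec",
    "fbcsp_branch_spec",
    "build_architecture",
    "shape_trace",
    "build_model",
    "build_full_model",
    "train",
    "predict",
    "elu",
    "maxpool",
    "softmax",
]

VARIANTS = ("full", "A", "B", "C", "D", "E")


@dataclass(frozen=True)
class LayerSpec:
    """Declarative layer: enough to trace shapes and build the real layer."""

    kind: str  # conv | maxpool | flatten | dense
    kernel: tuple[int, int] | None = None
    n_kernels: int | None = None
    units: int | None = None
    activation: str | None = None
    padding: str = "valid"

    def __post_init__(self) -> None:
        if self.kind == "conv" and (self.kernel is None or self.n_kernels is None):
            raise ValueError("conv spec needs kernel and n_kernels")
        if self.kind == "dense" and self.units is None:
            raise ValueError("dense spec needs units")
        if self.kernel is not None and min(self.kernel) < 1:
            raise ValueError("kernel dims must be positive")


def conv(kh: int, kw: int, n: int, padding: str) -> LayerSpec:
    return LayerSpec("conv", kernel=(kh, kw), n_kernels=n, activation="elu", padding=padding)


POOL = LayerSpec("maxpool", kernel=(2, 2))
FLAT = LayerSpec("flatten")


def dense(units: int, activation: str | None = "elu") -> LayerSpec:
    return LayerSpec("dense", units=units, activation=activation)


def mfcnn_branch_spec(extra_convs: bool = False) -> list[LayerSpec]:
    """Branch over one C x C brain-network layer (Conv 6x6@32 ... Dense 64)."""
    specs = [conv(6, 6, 32, "same"), POOL, conv(4, 4, 64, "same")]
    if extra_convs:
        specs.append(conv(4, 4, 64, "same"))
    specs.append(conv(3, 3, 64, "same"))
    if extra_convs:
        specs.append(conv(3, 3, 64, "same"))
    specs += [POOL, conv(3, 3, 64, "same"), FLAT, dense(64)]
    return specs


def fbcsp_branch_spec(first_kernel: tuple[int, int] = (3, 32)) -> list[LayerSpec]:
    """Branch over the bands x features image; band-fusing valid kernels."""
    return [
        conv(first_kernel[0], first_kernel[1], 32, "valid"),
        POOL,
        conv(3, 16, 64, "valid"),
        conv(2, 8, 64, "valid"),
        FLAT,
        dense(64),
    ]


@dataclass
class ArchitectureSpec:
    """Ordered branch declarations plus the fusion head."""

    branches: dict[str, list[LayerSpec]]
    head: list[LayerSpec]
    n_classes: int = 4


def build_architecture(variant: str = "full", n_classes: int = 4) -> ArchitectureSpec:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    branches: dict[str, list[LayerSpec]] = {}
    if variant != "A":
        branches["mu"] = mfcnn_branch_spec(extra_convs=(variant == "C"))
    if variant != "B":
        branches["beta"] = mfcnn_branch_spec(extra_convs=(variant == "D"))
    branches["fbcsp"] = fbcsp_branch_spec(first_kernel=(2, 32) if variant == "E" else (3, 32))
    return ArchitectureSpec(branches=branches, head=[dense(n_classes, activation=None)])


def shape_trace(specs: list[LayerSpec], input_shape: tuple[int, ...]) -> list[tuple[int, ...]]:
    """Arithmetic shape propagation, independent of the compute engine.

    valid conv: out = in - k + 1; same conv: out = in; 2x2 pool:
    out = floor(in / 2); flatten: product; dense: units.
    """
    shape = tuple(input_shape)
    trace = []
    for s in specs:
        if s.kind == "conv":
            h, w, _ = shape
            if s.padding == "same":
                shape = (h, w, s.n_kernels)
            else:
                kh, kw = s.kernel
                if h < kh or w < kw:
                    raise ValueError(f"input {shape} smaller than kernel {s.kernel}")
                shape = (h - kh + 1, w - kw + 1, s.n_kernels)
        elif s.kind == "maxpool":
            h, w, c = shape
            if h < 2 or w < 2:
                raise ValueError(f"input {shape} too small to pool")
            shape = (h // 2, w // 2, c)
        elif s.kind == "flatten":
            shape = (int(np.prod(shape)),)
        elif s.kind == "dense":
            shape = (s.units,)
        else:
            raise ValueError(f"unknown layer kind {s.kind!r}")
        trace.append(shape)
    return trace


def parameter_count(specs: list[LayerSpec], input_shape: tuple[int, ...],
                    learnable_lambda: bool = True) -> int:
    """Parameters implied by a spec list: pure arithmetic, no network built."""
    shape = tuple(input_shape)
    total = 0
    for s, out in zip(specs, shape_trace(specs, input_shape)):
        if s.kind == "conv":
            kh, kw = s.kernel
            total += kh * kw * shape[-1] * s.n_kernels + s.n_kernels
            total += int(learnable_lambda and s.activation == "elu")
        elif s.kind == "dense":
            total += shape[0] * s.units + s.units
            total += int(learnable_lambda and s.activation == "elu")
        shape = out
    return total


def _make_layer(s: LayerSpec, fixed_lambda: bool) -> Layer:
    if s.kind == "conv":
        return Conv2D(*s.kernel, s.n_kernels, padding=s.padding,
                      activation=s.activation, fixed_lambda=fixed_lambda)
    if s.kind == "maxpool":
        return MaxPool2D(s.kernel[0])
    if s.kind == "flatten":
        return Flatten()
    if s.kind == "dense":
        return Dense(s.units, activation=s.activation, fixed_lambda=fixed_lambda)
    raise ValueError(f"unknown layer kind {s.kind!r}")


def build_model(
    arch: ArchitectureSpec,
    input_shapes: dict[str, tuple[int, int]],
    seed: int = 0,
    fixed_lambda: bool = False,
) -> MultiBranchNet:
    """Instantiate a network from a declaration and build its weights."""
    missing = set(arch.branches) - set(input_shapes)
    if missing:
        raise ValueError(f"missing input shapes for branches: {sorted(missing)}")
    net = MultiBranchNet(
        branches={
            name: [_make_layer(s, fixed_lambda) for s in specs]
            for name, specs in arch.branches.items()
        },
        head=[_make_layer(s, fixed_lambda) for s in arch.head],
    )
    rng = np.random.default_rng(seed)
    net.build({k: (*v, 1) for k, v in input_shapes.items()}, rng)
    return net


def build_full_model(
    variant: str = "full",
    feature_width: int = 176,
    n_channels: int = 22,
    n_classes: int = 4,
    n_bands: int = 43,
    seed: int = 0,
    fixed_lambda: bool = False,
) -> MultiBranchNet:
    """Convenience builder: variant + feature-image width to a built network."""
    if feature_width < 32:
        raise ValueError("feature image width must be >= 32 (first FBCSP kernel)")
    arch = build_architecture(variant, n_classes)
    shapes: dict[str, tuple[int, int]] = {}
    if "mu" in arch.branches:
        shapes["mu"] = (n_channels, n_channels)
    if "beta" in arch.branches:
        shapes["beta"] = (n_channels, n_channels)
    shapes["fbcsp"] = (n_bands, feature_width)
    return build_model(arch, shapes, seed=seed, fixed_lambda=fixed_lambda)


# --------------------------------------------------------------- training


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("training hyperparameters must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _as_class_index(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    return labels - labels.min() if labels.min() >= 1 else labels


def train(
    model: MultiBranchNet,
    train_inputs: dict[str, np.ndarray],
    train_labels: np.ndarray,
    val_inputs: dict[str, np.ndarray],
    val_labels: np.ndarray,
    cfg: TrainConfig,
) -> TrainHistory:
    """Minimize cross-entropy with Adam; restore best-validation weights.

    Early stopping monitors validation accuracy (loss as tie-break) with
    ``cfg.patience``; deterministic given ``cfg.seed``.
    """
    if np.asarray(train_labels).size == 0 or np.asarray(val_labels).size == 0:
        raise ValueError("empty training or validation split")
    y_tr = _as_class_index(train_labels)
    y_va = _as_class_index(val_labels)
    n = y_tr.size
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(lr=cfg.learning_rate)
    hist = TrainHistory()
    best = (-np.inf, np.inf)  # (val_acc, -val_loss) maximization key
    best_weights = model.get_weights()
    since_best = 0
    for ep in range(cfg.max_epochs):
        perm = rng.permutation(n)
        ep_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            batch = {k: v[idx] for k, v in train_inputs.items()}
            logits = model.forward(batch)
            loss, g = cross_entropy_grad(logits, y_tr[idx])
            model.backward(g)
            opt.step(model.param_grads())
            ep_loss += loss * idx.size
        probs = model.predict_proba(val_inputs)
        val_loss = -float(
            np.mean(np.log(np.maximum(probs[np.arange(y_va.size), y_va], 1e-12)))
        )
        val_acc = float(np.mean(probs.argmax(axis=1) == y_va))
        hist.loss.append(ep_loss / n)
        hist.val_loss.append(val_loss)
        hist.val_acc.append(val_acc)
        key = (val_acc, -val_loss)
        if key > best:
            best = key
            best_weights = model.get_weights()
            hist.best_epoch = ep
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.set_weights(best_weights)
    return hist


def predict(model: MultiBranchNet, inputs: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (1-based) and softmax probabilities.

    ``argmax`` ties resolve toward the lower class index.
    """
    if not model.built:
        raise RuntimeError("model has not been built")
    probs = model.predict_proba(inputs)
    return probs.argmax(axis=1) + 1, probs
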