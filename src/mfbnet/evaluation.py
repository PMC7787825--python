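"""Split / train / evaluate protocol: accuracy, Cohen's kappa, ablations.

The protocol mirrors common motor-imagery practice: per run, a stratified
60/10/30 train/validation/test split, training with early stopping on the
validation split, test accuracy and chance-corrected agreement

    kappa = (p_o - p_e) / (1 - p_e),

with ``p_e = 1/n_classes`` for balanced designs (0.25 for 4 classes) or
computed from confusion-matrix marginals.  Results are averaged over
independently seeded runs; ablation variants reuse identical per-run splits
so comparisons are paired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mfbnet.dataset import EpochedDataset
from mfbnet.fbcsp import FBCSPFeatureExtractor
from mfbnet.models import TrainConfig, build_full_model, predict, train


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions; stratified and seeded."""

    train_fraction: float = 0.60
    val_fraction: float = 0.10
    test_fraction: float = 0.30
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions sum to {total}, expected 1")
        if min(self.train_fraction, self.val_fraction, self.test_fraction) < 0:
            raise ValueError("split fractions must be non-negative")


def _allocate(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    n_tr = int(round(spec.train_fraction * n))
    n_va = int(round(spec.val_fraction * n))
    n_te = n - n_tr - n_va
    if min(n_tr, n_va, n_te) < 1:
        raise ValueError(f"cannot split {n} trials into non-empty {spec}")
    return n_tr, n_va, n_te


def split_indices(labels: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, val, test) index arrays."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    groups = [np.where(labels == k)[0] for k in np.unique(labels)] if spec.stratified else [
        np.arange(labels.size)
    ]
    tr, va, te = [], [], []
    for g in groups:
        g = rng.permutation(g)
        n_tr, n_va, _ = _allocate(g.size, spec)
        tr.append(g[:n_tr])
        va.append(g[n_tr : n_tr + n_va])
        te.append(g[n_tr + n_va :])
    return tuple(np.sort(np.concatenate(p)) for p in (tr, va, te))


def split(
    dataset: EpochedDataset, spec: SplitSpec
) -> tuple[EpochedDataset, EpochedDataset, EpochedDataset]:
    """Dataset-level split; see :func:`split_indices`."""
    tr, va, te = split_indices(dataset.labels, spec)
    return dataset.select(tr), dataset.select(va), dataset.select(te)


# ----------------------------------------------------------------- kappa


def kappa(p_o: float, p_e: float = 0.25) -> float:
    """Cohen's kappa from observed and chance agreement proportions."""
    if not (0 <= p_o <= 1):
        raise ValueError(f"p_o={p_o} outside [0, 1]")
    if not (0 <= p_e < 1):
        raise ValueError(f"p_e={p_e} outside [0, 1); kappa undefined at p_e=1")
    return (p_o - p_e) / (1 - p_e)


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Rows = true class, columns = predicted class (labels 1-based or 0-based)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    lo = min(y_true.min(), y_pred.min())
    n = n_classes or int(max(y_true.max(), y_pred.max()) - lo + 1)
    cm = np.zeros((n, n), dtype=int)
    for t, p in zip(y_true - lo, y_pred - lo):
        cm[t, p] += 1
    return cm


def kappa_from_confusion(cm: np.ndarray) -> float:
    """Kappa with chance agreement from the confusion-matrix marginals."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float(cm.sum(axis=1) @ cm.sum(axis=0)) / total**2
    return kappa(p_o, p_e)


# ---------------------------------------------------------------- report


@dataclass
class EvalReport:
    """Per-run and aggregate accuracy/kappa for one model variant."""

    variant: str
    accuracies: list[float] = field(default_factory=list)
    kappas: list[float] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    confusions: list[np.ndarray] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.accuracies)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if self.n_runs > 1 else 0.0

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.kappas))

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_runs": self.n_runs,
            "accuracies": self.accuracies,
            "kappas": self.kappas,
            "seeds": self.seeds,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_kappa": self.mean_kappa,
        }

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        with open(stem.with_suffix(".json"), "w") as f:
            json.dump(self.to_dict(), f, indent=2)
        pd.DataFrame(
            {"seed": self.seeds, "accuracy": self.accuracies, "kappa": self.kappas}
        ).to_csv(stem.with_suffix(".csv"), index=False)
        for i, cm in enumerate(self.confusions):
            pd.DataFrame(cm).to_csv(stem.parent / f"{stem.name}_confusion_run{i}.csv", index=False)


# -------------------------------------------------------------- protocol


def _standardize_rows(images: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    """Standardize each band row with training-set statistics."""
    mu = images[train_idx].mean(axis=(0, 2))
    sd = images[train_idx].std(axis=(0, 2))
    return (images - mu[None, :, None]) / np.maximum(sd[None, :, None], 1e-12)


def _model_inputs(networks: np.ndarray, images: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "mu": networks[:, 0, :, :, None].astype(np.float32),
        "beta": networks[:, 1, :, :, None].astype(np.float32),
        "fbcsp": images[..., None].astype(np.float32),
    }


def run_single(
    networks: np.ndarray,
    labels: np.ndarray,
    extractor: FBCSPFeatureExtractor,
    variant: str,
    seed: int,
    train_cfg: TrainConfig,
    split_spec: SplitSpec | None = None,
) -> tuple[float, float, np.ndarray]:
    """One split + train + test cycle; returns (accuracy, kappa, confusion)."""
    spec = split_spec or SplitSpec(seed=seed)
    tr, va, te = split_indices(labels, spec)
    extractor.fit(tr)
    images = _standardize_rows(extractor.transform(), tr)
    inputs = _model_inputs(networks, images)
    model = build_full_model(
        variant,
        feature_width=images.shape[2],
        n_channels=networks.shape[2],
        n_classes=int(np.unique(labels).size),
        n_bands=images.shape[1],
        seed=seed,
    )
    cfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed})
    train(
        model,
        {k: v[tr] for k, v in inputs.items()},
        labels[tr],
        {k: v[va] for k, v in inputs.items()},
        labels[va],
        cfg,
    )
    pred, _ = predict(model, {k: v[te] for k, v in inputs.items()})
    acc = float(np.mean(pred == labels[te]))
    cm = confusion_matrix(labels[te], pred, n_classes=int(np.unique(labels).size))
    return acc, kappa(acc), cm


def run_protocol(
    networks: np.ndarray,
    labels: np.ndarray,
    extractor: FBCSPFeatureExtractor,
    variant: str = "full",
    n_runs: int = 10,
    base_seed: int = 0,
    train_cfg: TrainConfig | None = None,
    split_spec: SplitSpec | None = None,
) -> EvalReport:
    """Repeat independent split/train/test cycles and aggregate.

    Run ``r`` uses seed ``base_seed + r`` for its split, weight
    initialization and batch order, so the whole report is reproducible
    from ``base_seed`` alone.
    """
    train_cfg = train_cfg or TrainConfig()
    report = EvalReport(variant=variant)
    for r in range(n_runs):
        seed = base_seed + r
        spec = SplitSpec(seed=seed) if split_spec is None else SplitSpec(
            **{**split_spec.__dict__, "seed": seed}
        )
        acc, kap, cm = run_single(networks, labels, extractor, variant, seed, train_cfg, spec)
        report.accuracies.append(acc)
        report.kappas.append(kap)
        report.seeds.append(seed)
        report.confusions.append(cm)
    return report


def ablation_suite(
    networks: np.ndarray,
    labels: np.ndarray,
    extractor: FBCSPFeatureExtractor,
    variants: tuple[str, ...] = ("full", "A", "B", "C", "D", "E"),
    n_runs: int = 10,
    base_seed: int = 0,
    train_cfg: TrainConfig | None = None,
    split_spec: SplitSpec | None = None,
) -> list[EvalReport]:
    """One report per variant with identical per-run splits (paired design)."""
    return [
        run_protocol(
            networks, labels, extractor, v, n_runs, base_seed, train_cfg, split_spec
        )
        for v in variants
    ]
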