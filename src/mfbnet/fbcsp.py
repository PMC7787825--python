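"""One-versus-rest filter-bank common spatial patterns (OVR-FBCSP).

For each filter-bank band, CSP finds spatial filters maximizing the variance
of one class relative to the pool of all classes.  With class-mean
trace-normalized covariances ``P_k`` this is the generalized eigenproblem

    P_k w = lambda (sum_j P_j) w,

whose eigenvalues lie in [0, 1]; the eigenvector matrix whitens the pooled
covariance.  Per trial, band and time window the features are the log10 of
the normalized variances of the first and last ``m`` spatially filtered
components, and all (band x window x class x 2m) values are reorganised into
a 2-D feature image with one row per band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from mfbnet.dataset import EpochedDataset
from mfbnet.preprocessing import (
    FilterBankSpec,
    TimeWindow,
    bandpass_array,
    build_filter_bank,
    DEFAULT_WINDOWS,
)

DEFAULT_RIDGE = 1e-8


@dataclass
class OVRProjection:
    """Per-class CSP eigenvector matrices for one frequency band.

    ``filters[k]`` is the C x C eigenvector matrix of class ``k`` (columns
    sorted by descending eigenvalue); ``eigvals[k]`` the matching
    eigenvalues.  Keys are the class labels seen at fit time.
    """

    filters: dict[int, np.ndarray]
    eigvals: dict[int, np.ndarray]

    @property
    def classes(self) -> list[int]:
        return sorted(self.filters)


def trial_covariance(x: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance ``X X^T / tr(X X^T)``.

    Trace normalization removes per-trial amplitude scale, so trials with
    different overall power contribute equally to class means.
    """
    x = np.asarray(x, dtype=float)
    c = x @ x.T
    tr = np.trace(c)
    if tr <= 0:
        raise ValueError("zero-variance trial: covariance trace is 0")
    return c / tr


def fit_ovr_csp(
    data: np.ndarray,
    labels: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
) -> OVRProjection:
    """Fit one-versus-rest CSP filters on band-filtered trials.

    Parameters
    ----------
    data : ndarray (n_trials, C, S)
        Trials already filtered to one band.
    labels : ndarray (n_trials,)
    ridge : float
        Relative ridge added to the pooled covariance for conditioning.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    cov_sums: dict[int, np.ndarray] = {}
    for k in classes:
        idx = np.where(labels == k)[0]
        if idx.size < 2:
            raise ValueError(f"class {k} has fewer than 2 trials")
        cov_sums[int(k)] = np.mean([trial_covariance(data[t]) for t in idx], axis=0)
    return _solve_ovr(cov_sums, ridge)


def fit_ovr_csp_from_covariances(
    class_means: dict[int, np.ndarray], ridge: float = DEFAULT_RIDGE
) -> OVRProjection:
    """As :func:`fit_ovr_csp` but from precomputed class-mean covariances."""
    return _solve_ovr(class_means, ridge)


def _solve_ovr(class_means: dict[int, np.ndarray], ridge: float) -> OVRProjection:
    pooled = np.sum(list(class_means.values()), axis=0)
    c = pooled.shape[0]
    pooled = pooled + ridge * np.trace(pooled) / c * np.eye(c)
    filters, eigvals = {}, {}
    for k, pk in class_means.items():
        try:
            w, v = linalg.eigh(pk, pooled)
        except linalg.LinAlgError as e:  # pragma: no cover - defensive
            raise linalg.LinAlgError(
                "singular pooled covariance; increase the ridge regularization"
            ) from e
        order = np.argsort(w)[::-1]
        filters[int(k)] = v[:, order]
        eigvals[int(k)] = np.clip(w[order], 0.0, 1.0)
    return OVRProjection(filters=filters, eigvals=eigvals)


def spatial_filter(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Project a trial onto spatial components: ``W^T X``."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape[0] != x.shape[0]:
        raise ValueError(f"filter rows {w.shape[0]} != channels {x.shape[0]}")
    return w.T @ x


def csp_features(x: np.ndarray, w_k: np.ndarray, m: int = 2) -> np.ndarray:
    """Log-variance CSP features of one trial for one class filter.

    Keeps the first ``m`` and last ``m`` eigenvector columns (the most
    discriminative components for class vs rest), computes their variance
    shares and returns ``log10`` of the resulting length-2m probability
    vector.
    """
    if w_k.shape[1] < 2 * m:
        raise ValueError(f"filter has {w_k.shape[1]} columns, need >= {2 * m}")
    w_tilde = np.concatenate([w_k[:, :m], w_k[:, -m:]], axis=1)
    y = spatial_filter(x, w_tilde)
    v = np.sum(y * y, axis=1)
    tot = v.sum()
    if tot <= 0 or np.any(v <= 0):
        raise ValueError("zero-variance projected component")
    return np.log10(v / tot)


def feature_width(n_windows: int, n_classes: int, m: int) -> int:
    """Number of columns of the feature image."""
    return n_windows * n_classes * 2 * m


def assemble_feature_image(
    dataset: EpochedDataset,
    bank: FilterBankSpec,
    windows: tuple[TimeWindow, ...],
    projections: list[OVRProjection],
    m: int = 2,
) -> np.ndarray:
    """Per-trial 2-D feature images, shape ``(n_trials, n_bands, F)``.

    Rows follow the filter-bank band order; columns are window-major, then
    class-major, then the 2m log-variance features.  ``projections`` must
    supply one fitted :class:`OVRProjection` per band (fitted on training
    trials only).
    """
    if len(projections) != bank.n_bands:
        raise ValueError(
            f"need one projection per band: got {len(projections)} for {bank.n_bands} bands"
        )
    classes = projections[0].classes
    f_width = feature_width(len(windows), len(classes), m)
    images = np.empty((dataset.n_trials, bank.n_bands, f_width))
    for b, band in enumerate(bank.bands):
        filt = bandpass_array(
            dataset.data, band, dataset.fs, bank.order, bank.stopband_db, bank.transition_hz
        )
        proj = projections[b]
        col = 0
        for win in windows:
            i0 = int(round((win.start - dataset.t0) * dataset.fs))
            n = win.n_samples(dataset.fs)
            seg = filt[:, :, i0 : i0 + n]
            for k in classes:
                for t in range(dataset.n_trials):
                    images[t, b, col : col + 2 * m] = csp_features(seg[t], proj.filters[k], m)
                col += 2 * m
    return images


class FBCSPFeatureExtractor:
    """Filter-bank CSP feature images with cached per-band covariances.

    Filtering all trials through 43 bands dominates the cost of feature
    extraction, and does not depend on the train/test split.  This class
    filters once, caches the per-(band, window, trial) scatter matrices
    ``X X^T`` plus full-segment trace-normalized covariances, and then lets
    ``fit`` / ``transform`` re-derive projections and images for any split
    cheaply — the pattern needed for 10-run protocols.

    Train/test hygiene: ``fit(train_idx)`` uses only the given trials;
    ``transform`` merely projects, so applying training-fitted filters to
    held-out trials leaks nothing.
    """

    def __init__(
        self,
        bank: FilterBankSpec | None = None,
        windows: tuple[TimeWindow, ...] = DEFAULT_WINDOWS,
        m: int = 2,
        fit_window: TimeWindow | None = None,
        ridge: float = DEFAULT_RIDGE,
    ) -> None:
        self.bank = bank or build_filter_bank()
        self.windows = tuple(windows)
        self.m = m
        #: Segment on which projections are fitted; defaults to the span of
        #: all analysis windows (the full motor-imagery period).
        self.fit_window = fit_window or TimeWindow(
            min(w.start for w in self.windows), max(w.end for w in self.windows)
        )
        self.ridge = ridge
        self._scatter: np.ndarray | None = None  # (B, W, T, C, C)
        self._fit_cov: np.ndarray | None = None  # (B, T, C, C) trace-normalized
        self._labels: np.ndarray | None = None
        self.projections_: list[OVRProjection] | None = None

    # -------------------------------------------------------------- stage 1

    def precompute(self, dataset: EpochedDataset) -> "FBCSPFeatureExtractor":
        """Filter every trial through every band and cache scatter matrices."""
        t_, c_, _ = dataset.data.shape
        b_, w_ = self.bank.n_bands, len(self.windows)
        self._scatter = np.empty((b_, w_, t_, c_, c_), dtype=np.float64)
        self._fit_cov = np.empty((b_, t_, c_, c_), dtype=np.float64)
        self._labels = dataset.labels.copy()
        fs, t0 = dataset.fs, dataset.t0
        for b, band in enumerate(self.bank.bands):
            filt = bandpass_array(
                dataset.data, band, fs, self.bank.order, self.bank.stopband_db,
                self.bank.transition_hz,
            )
            for w, win in enumerate(self.windows):
                i0 = int(round((win.start - t0) * fs))
                seg = filt[:, :, i0 : i0 + win.n_samples(fs)]
                self._scatter[b, w] = np.einsum("tcs,tds->tcd", seg, seg)
            i0 = int(round((self.fit_window.start - t0) * fs))
            seg = filt[:, :, i0 : i0 + self.fit_window.n_samples(fs)]
            cov = np.einsum("tcs,tds->tcd", seg, seg)
            tr = np.trace(cov, axis1=1, axis2=2)
            self._fit_cov[b] = cov / tr[:, None, None]
        return self

    # -------------------------------------------------------------- stage 2

    def fit(self, train_idx: np.ndarray) -> "FBCSPFeatureExtractor":
        """Fit per-band OVR projections from training trials only."""
        if self._fit_cov is None:
            raise RuntimeError("call precompute(dataset) first")
        train_idx = np.asarray(train_idx, dtype=int)
        labels = self._labels[train_idx]
        self.projections_ = []
        for b in range(self.bank.n_bands):
            means = {
                int(k): self._fit_cov[b, train_idx[labels == k]].mean(axis=0)
                for k in np.unique(labels)
            }
            self.projections_.append(fit_ovr_csp_from_covariances(means, self.ridge))
        return self

    def transform(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Feature images ``(n_trials, n_bands, F)`` for the given trials."""
        if self.projections_ is None:
            raise RuntimeError("call fit(train_idx) first")
        idx = np.arange(self._scatter.shape[2]) if idx is None else np.asarray(idx, dtype=int)
        b_, w_ = self.bank.n_bands, len(self.windows)
        classes = self.projections_[0].classes
        m = self.m
        images = np.empty((idx.size, b_, feature_width(w_, len(classes), m)))
        for b in range(b_):
            proj = self.projections_[b]
            col = 0
            for w in range(w_):
                s = self._scatter[b, w][idx]  # (T, C, C)
                for k in classes:
                    wk = proj.filters[k]
                    w_tilde = np.concatenate([wk[:, :m], wk[:, -m:]], axis=1)
                    v = np.einsum("ci,tcd,di->ti", w_tilde, s, w_tilde)
                    v = np.maximum(v, 1e-300)
                    images[:, b, col : col + 2 * m] = np.log10(v / v.sum(axis=1, keepdims=True))
                    col += 2 * m
        return images
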