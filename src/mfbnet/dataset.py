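"""Epoched EEG container and HDF5/CSV I/O.

``EpochedDataset`` is the exchange object every pipeline stage consumes and
produces: a ``(trials, channels, samples)`` array with class labels, sampling
rate, channel names and the time of sample 0 relative to trial onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


@dataclass
class EpochedDataset:
    """Epoched multichannel EEG trials with labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal amplitudes (arbitrary units, typically microvolts).
    labels : ndarray, shape (n_trials,)
        Integer class label per trial (1-based task codes).
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per channel.
    t0 : float
        Time of sample 0 in seconds, relative to trial onset.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, channels, samples), got {self.data.ndim}-D")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match trial count {self.data.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match channel count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to trial onset."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy_with(self, data: np.ndarray, t0: float | None = None) -> "EpochedDataset":
        """New dataset sharing labels/metadata but with replaced signal array."""
        return EpochedDataset(
            data=data,
            labels=self.labels.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            t0=self.t0 if t0 is None else t0,
        )

    def select(self, idx: np.ndarray) -> "EpochedDataset":
        """Subset of trials by index array."""
        idx = np.asarray(idx, dtype=int)
        return EpochedDataset(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            t0=self.t0,
        )

    # ------------------------------------------------------------------ I/O

    def save(self, path: str | Path, labels_csv: str | Path | None = None, **attrs) -> None:
        """Write to HDF5 (``/data``, ``/labels``) plus optional label CSV."""
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("labels", data=self.labels)
            f.attrs["fs"] = self.fs
            f.attrs["t0"] = self.t0
            f.attrs["channel_names"] = [str(c) for c in self.channel_names]
            for k, v in attrs.items():
                f.attrs[k] = v
        if labels_csv is not None:
            df = pd.DataFrame({"trial_id": np.arange(self.n_trials), "label": self.labels})
            df.to_csv(labels_csv, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "EpochedDataset":
        with h5py.File(path, "r") as f:
            names = [
                c.decode() if isinstance(c, bytes) else str(c) for c in f.attrs["channel_names"]
            ]
            return cls(
                data=f["data"][()],
                labels=f["labels"][()],
                fs=float(f.attrs["fs"]),
                channel_names=names,
                t0=float(f.attrs["t0"]),
            )
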