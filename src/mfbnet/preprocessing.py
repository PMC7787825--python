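"""Epoching, bandpass filtering, the 43-band filter bank and time windows.

Filtering uses zero-phase (forward-backward) Chebyshev Type II designs: a
monotone passband and an explicit stopband attenuation, which is the usual
choice for FBCSP-style filter banks where adjacent bands overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from mfbnet.dataset import EpochedDataset


@dataclass(frozen=True)
class BandSpec:
    """A passband in Hz."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band ({self.low}, {self.high})")

    @property
    def width(self) -> float:
        return self.high - self.low

    def validate_for_fs(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(f"band edge {self.high} Hz >= Nyquist ({fs / 2} Hz)")


#: Sensorimotor rhythms dominating motor-imagery ERD/ERS.
MU_BAND = BandSpec(8.0, 12.0)
BETA_BAND = BandSpec(18.0, 24.0)


@dataclass(frozen=True)
class TimeWindow:
    """A time window in seconds relative to trial onset."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window start {self.start} must precede end {self.end}")

    def n_samples(self, fs: float) -> int:
        return int(round((self.end - self.start) * fs))


#: The 11 analysis windows covering the motor-imagery period (2.5-6 s):
#: six sliding 1 s windows, four sliding 2 s windows, and the full segment.
DEFAULT_WINDOWS: tuple[TimeWindow, ...] = tuple(
    TimeWindow(s, e)
    for s, e in [
        (2.5, 3.5), (3.0, 4.0), (3.5, 4.5), (4.0, 5.0), (4.5, 5.5), (5.0, 6.0),
        (2.5, 4.5), (3.0, 5.0), (3.5, 5.5), (4.0, 6.0), (2.5, 6.0),
    ]
)


@dataclass(frozen=True)
class FilterBankSpec:
    """An ordered list of passbands plus the shared filter design.

    The default design is Chebyshev Type II, order 4 (effective order 8 after
    forward-backward filtering), 30 dB stopband attenuation and a 2 Hz
    transition from passband edge to stopband edge.
    """

    bands: tuple[BandSpec, ...]
    family: str = "cheby2"
    order: int = 4
    stopband_db: float = 30.0
    transition_hz: float = 2.0

    @property
    def n_bands(self) -> int:
        return len(self.bands)


def design_bandpass(
    band: BandSpec,
    fs: float,
    order: int = 4,
    stopband_db: float = 30.0,
    transition_hz: float = 2.0,
) -> np.ndarray:
    """Chebyshev-II bandpass as second-order sections.

    The stopband edges sit ``transition_hz`` outside the passband, clipped
    away from DC and Nyquist.
    """
    band.validate_for_fs(fs)
    lo = max(band.low - transition_hz, 0.25)
    hi = min(band.high + transition_hz, fs / 2 - 0.25)
    return signal.cheby2(order, stopband_db, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_array(
    data: np.ndarray,
    band: BandSpec,
    fs: float,
    order: int = 4,
    stopband_db: float = 30.0,
    transition_hz: float = 2.0,
) -> np.ndarray:
    """Zero-phase bandpass along the last axis."""
    sos = design_bandpass(band, fs, order, stopband_db, transition_hz)
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass(epochs: EpochedDataset, band: BandSpec, **design_kwargs) -> EpochedDataset:
    """Zero-phase bandpass of every channel of every trial."""
    return epochs.copy_with(bandpass_array(epochs.data, band, epochs.fs, **design_kwargs))


def epoch(
    raw: np.ndarray,
    events: list[tuple[float, int]],
    t_start: float,
    t_end: float,
    fs: float,
    channel_names: list[str] | None = None,
) -> EpochedDataset:
    """Cut trials ``[onset + t_start, onset + t_end)`` from a continuous recording.

    Parameters
    ----------
    raw : ndarray, shape (n_channels, n_samples)
    events : list of (onset_seconds, label)
    t_start, t_end : float
        Epoch limits in seconds relative to each event onset.

    Overlapping events are extracted independently.  Any event whose window
    falls outside the recording raises, naming the offending onsets.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw must be (channels, samples)")
    if t_start >= t_end:
        raise ValueError("t_start must precede t_end")
    n_win = int(round((t_end - t_start) * fs))
    trials, labels, bad = [], [], []
    for onset, label in events:
        i0 = int(round((onset + t_start) * fs))
        if i0 < 0 or i0 + n_win > raw.shape[1]:
            bad.append(onset)
            continue
        trials.append(raw[:, i0 : i0 + n_win])
        labels.append(label)
    if bad:
        raise ValueError(f"event windows out of bounds for onsets (s): {bad}")
    data = np.stack(trials) if trials else np.empty((0, raw.shape[0], n_win))
    return EpochedDataset(
        data=data,
        labels=np.asarray(labels, dtype=int),
        fs=fs,
        channel_names=list(channel_names) if channel_names else [],
        t0=t_start,
    )


def build_filter_bank(
    fmin: float = 4.0,
    fmax: float = 40.0,
    scheme: str = "multiscale43",
    **design_kwargs,
) -> FilterBankSpec:
    """Construct the filter bank covering ``[fmin, fmax]``.

    The default ``multiscale43`` scheme stacks five band-width scales:
    4 Hz wide bands stepped by 2 Hz (17 bands), then 8, 12, 16 and 20 Hz
    wide bands each stepped by 4 Hz (8 + 7 + 6 + 5 bands), 43 in total,
    ordered by (width, low edge).  Narrow bands localise rhythms precisely;
    wide bands keep broadband discriminative power.
    """
    if fmin >= fmax:
        raise ValueError("fmin must be below fmax")
    if scheme != "multiscale43":
        raise ValueError(f"unknown filter-bank scheme {scheme!r}")
    bands: list[BandSpec] = []
    for width, step in [(4.0, 2.0), (8.0, 4.0), (12.0, 4.0), (16.0, 4.0), (20.0, 4.0)]:
        lo = fmin
        while lo + width <= fmax + 1e-9:
            bands.append(BandSpec(lo, lo + width))
            lo += step
    return FilterBankSpec(bands=tuple(bands), **design_kwargs)


def slice_time_windows(
    epochs: EpochedDataset, windows: list[TimeWindow] | tuple[TimeWindow, ...]
) -> list[EpochedDataset]:
    """One sliced dataset per window; window times are relative to trial onset."""
    out = []
    for k, w in enumerate(windows):
        i0 = int(round((w.start - epochs.t0) * epochs.fs))
        n = w.n_samples(epochs.fs)
        if i0 < 0 or i0 + n > epochs.n_samples:
            raise ValueError(
                f"window {k} ({w.start}-{w.end} s) outside trial extent "
                f"[{epochs.t0}, {epochs.t0 + epochs.n_samples / epochs.fs}] s"
            )
        out.append(epochs.copy_with(epochs.data[:, :, i0 : i0 + n], t0=w.start))
    return out
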