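"""Phase-locking connectivity and multilayer brain-network assembly.

Each trial becomes a stack of sparsified weighted adjacency matrices, one
layer per frequency band (mu, beta by default).  Edges are phase-locking
values (PLV) between channel pairs: the modulus of the time-averaged unit
phasor of the instantaneous phase difference,

    PLV(x, y) = | < exp(i (phi_x(t) - phi_y(t))) >_t |  in [0, 1],

with instantaneous phase taken from the analytic signal (Hilbert transform).
PLV depends only on phases, never amplitudes.  Within each layer the weakest
75% of links are discarded (proportional thresholding), keeping weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.signal import hilbert

from mfbnet.dataset import EpochedDataset
from mfbnet.preprocessing import BandSpec, MU_BAND, BETA_BAND, bandpass_array

#: Fraction of samples trimmed from each end before phase statistics; the
#: Hilbert transform is unreliable near signal boundaries.
DEFAULT_EDGE_TRIM = 0.1


@dataclass
class AnalyticSignal:
    """Instantaneous amplitude and phase of a real signal."""

    amplitude: np.ndarray
    phase: np.ndarray


@dataclass
class MultilayerNetwork:
    """Per-trial stack of sparsified PLV layers, one per band."""

    layers: np.ndarray  # (n_layers, C, C)
    bands: tuple[BandSpec, ...]
    keep_fraction: float

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_channels(self) -> int:
        return self.layers.shape[1]


def analytic_signal(x: np.ndarray) -> AnalyticSignal:
    """Analytic-signal amplitude and phase via the Hilbert transform.

    The analytic extension ``z = x + i H[x]`` shifts every frequency
    component by 90 degrees in its imaginary part; amplitude is ``|z|`` and
    phase the four-quadrant angle of ``z``.  An all-zero signal has phase 0
    by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("signal too short for analytic-signal estimation")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN or Inf")
    z = hilbert(x, axis=-1)
    return AnalyticSignal(amplitude=np.abs(z), phase=np.angle(z))


def plv(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase-locking value from two instantaneous-phase series."""
    phase_x = np.asarray(phase_x, dtype=float)
    phase_y = np.asarray(phase_y, dtype=float)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase series must have equal length")
    if phase_x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.exp(1j * (phase_x - phase_y)))))


def _trim_slice(n: int, edge_trim: float) -> slice:
    k = int(n * edge_trim)
    return slice(k, n - k)


def plv_matrix(
    trial: np.ndarray,
    band: BandSpec,
    fs: float,
    edge_trim: float = DEFAULT_EDGE_TRIM,
    prefiltered: bool = False,
) -> np.ndarray:
    """Pairwise PLV matrix of one trial in one band.

    The trial is bandpass filtered (unless ``prefiltered``), phases are
    extracted channel-wise and trimmed at both ends, and all pairs are
    averaged at once via the unit-phasor Gram matrix.  Symmetric with unit
    diagonal.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2 or trial.shape[0] < 2:
        raise ValueError("trial must be (channels >= 2, samples)")
    if not prefiltered:
        trial = bandpass_array(trial, band, fs)
    phase = analytic_signal(trial).phase[:, _trim_slice(trial.shape[1], edge_trim)]
    phasors = np.exp(1j * phase)
    m = np.abs(phasors @ phasors.conj().T) / phase.shape[1]
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return np.clip(m, 0.0, 1.0)


def link_quota(n_channels: int, keep_fraction: float) -> int:
    """Number of upper-triangle links retained at a given keep fraction."""
    return ceil(keep_fraction * n_channels * (n_channels - 1) / 2)


def threshold_network(m: np.ndarray, keep_fraction: float = 0.25) -> np.ndarray:
    """Discard the weakest links, keeping the top ``keep_fraction`` by weight.

    Upper-triangle off-diagonal entries are ranked by weight (descending),
    ties broken by (row, col) lexicographic order; exactly
    ``ceil(keep_fraction * C(C-1)/2)`` survive with their weights.  The
    diagonal is zeroed and the result re-symmetrised.  Idempotent.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    c = m.shape[0]
    ii, jj = np.triu_indices(c, k=1)
    ww = m[ii, jj]
    # lexsort: last key is primary -> weight desc, then row, then col
    order = np.lexsort((jj, ii, -ww))
    quota = link_quota(c, keep_fraction)
    keep = order[:quota]
    out = np.zeros_like(m)
    out[ii[keep], jj[keep]] = ww[keep]
    return out + out.T


def build_multilayer(
    trial: np.ndarray,
    fs: float,
    bands: tuple[BandSpec, ...] = (MU_BAND, BETA_BAND),
    keep_fraction: float = 0.25,
    edge_trim: float = DEFAULT_EDGE_TRIM,
) -> MultilayerNetwork:
    """Thresholded PLV layer per band, in band order."""
    layers = np.stack(
        [
            threshold_network(plv_matrix(trial, b, fs, edge_trim=edge_trim), keep_fraction)
            for b in bands
        ]
    )
    return MultilayerNetwork(layers=layers, bands=tuple(bands), keep_fraction=keep_fraction)


def networks_from_dataset(
    dataset: EpochedDataset,
    bands: tuple[BandSpec, ...] = (MU_BAND, BETA_BAND),
    keep_fraction: float = 0.25,
    edge_trim: float = DEFAULT_EDGE_TRIM,
) -> np.ndarray:
    """Multilayer networks for every trial, vectorised per band.

    Returns an array of shape ``(n_trials, n_bands, C, C)``.
    """
    t_, c_, n_ = dataset.data.shape
    out = np.zeros((t_, len(bands), c_, c_))
    sl = _trim_slice(n_, edge_trim)
    for b_idx, band in enumerate(bands):
        filt = bandpass_array(dataset.data, band, dataset.fs)
        phase = np.angle(hilbert(filt, axis=-1))[:, :, sl]
        phasors = np.exp(1j * phase)
        gram = np.abs(np.einsum("tcn,tdn->tcd", phasors, phasors.conj())) / phase.shape[-1]
        for t in range(t_):
            m = 0.5 * (gram[t] + gram[t].T)
            np.fill_diagonal(m, 1.0)
            out[t, b_idx] = threshold_network(np.clip(m, 0, 1), keep_fraction)
    return out


# ---------------------------------------------------------------- exports


def export_edge_list(
    network: MultilayerNetwork, channel_names: list[str], path: str | Path
) -> pd.DataFrame:
    """Weighted edge list CSV: band, node_i, node_j, weight."""
    rows = []
    for layer, band in zip(network.layers, network.bands):
        ii, jj = np.nonzero(np.triu(layer, k=1))
        for i, j in zip(ii, jj):
            rows.append(
                {
                    "band": f"{band.low:g}-{band.high:g}Hz",
                    "node_i": channel_names[i],
                    "node_j": channel_names[j],
                    "weight": layer[i, j],
                }
            )
    df = pd.DataFrame(rows, columns=["band", "node_i", "node_j", "weight"])
    df.to_csv(path, index=False)
    return df


def to_graphml(network: MultilayerNetwork, channel_names: list[str], path: str | Path) -> None:
    """Multigraph export with one edge key per band layer."""
    g = nx.MultiGraph()
    g.add_nodes_from(channel_names)
    for layer, band in zip(network.layers, network.bands):
        tag = f"{band.low:g}-{band.high:g}Hz"
        ii, jj = np.nonzero(np.triu(layer, k=1))
        for i, j in zip(ii, jj):
            g.add_edge(channel_names[i], channel_names[j], key=tag, weight=float(layer[i, j]), band=tag)
    nx.write_graphml(g, path)
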