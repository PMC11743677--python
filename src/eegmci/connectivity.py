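"""Pairwise functional-connectivity features.

Three measures over all channel pairs, each evaluated in six frequency
bands (broadband 0.5-45 Hz plus the five canonical bands):

* **Pearson correlation** of the band-filtered time series — linear
  zero-lag coupling;
* **phase lag index (PLI)** — ``|mean_t sign(sin(phi_x(t) - phi_y(t)))|``
  with instantaneous phases from the analytic (Hilbert) signal of the
  band-filtered data; insensitive to zero-lag (volume-conducted) mixing
  because phase differences of 0 or pi contribute nothing;
* **magnitude-squared coherence (MSC)** — ``|S_xy|^2 / (S_xx S_yy)`` on
  the Welch cross-spectral grid, averaged over in-band bins.

Matrices are symmetric with the conventional diagonal (1 for Pearson and
MSC, 0 for PLI); the strict upper triangle in channel order vectorizes
each matrix into 120 features for a 16-channel montage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .bands import band_interval
from .preprocessing import Epoch, fir_bandpass, apply_zero_phase

__all__ = [
    "ConnectivityMatrix",
    "band_filter",
    "pearson_connectivity",
    "pli",
    "msc",
    "vectorize_connectivity",
    "connectivity_feature_table",
]

CONNECTIVITY_BAND_ORDER = ("full", "delta", "theta", "alpha", "beta", "gamma")

#: fraction of samples discarded at each end before averaging phase signs
_PLI_EDGE_FRACTION = 0.05


@dataclass
class ConnectivityMatrix:
    """Symmetric channels-x-channels connectivity values for one measure/band."""

    measure: str  # 'pearson' | 'pli' | 'msc'
    band: str
    values: np.ndarray
    channel_names: Sequence[str]

    def __post_init__(self) -> None:
        n = len(self.channel_names)
        if self.values.shape != (n, n):
            raise ValueError("values must be (channels x channels)")


def band_filter(epoch: Epoch, band: str) -> Epoch:
    """Zero-phase FIR band-pass of an epoch restricted to a named band."""
    low, high = band_interval(band)
    if high >= epoch.fs / 2:
        raise ValueError(
            f"band {band!r} upper edge {high} Hz is not below Nyquist "
            f"({epoch.fs / 2:g} Hz)"
        )
    taps = fir_bandpass(low, high, epoch.fs, epoch.n_samples)
    return Epoch(
        subject_id=epoch.subject_id,
        group=epoch.group,
        epoch_index=epoch.epoch_index,
        channel_names=epoch.channel_names,
        fs=epoch.fs,
        data=apply_zero_phase(epoch.data, taps),
    )


def pearson_connectivity(epoch: Epoch) -> ConnectivityMatrix:
    """Product-moment correlation matrix (unit diagonal).

    Channels with zero variance yield NaN in their off-diagonal entries.
    """
    if epoch.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sd = epoch.data.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(epoch.data)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix("pearson", "unfiltered", r, epoch.channel_names)


def pli(epoch: Epoch, band: str | None = None) -> ConnectivityMatrix:
    """Phase lag index matrix (zero diagonal) from the analytic signal.

    When ``band`` is given the epoch is band-filtered first; 5% of
    samples at each edge are discarded before averaging to suppress
    Hilbert-transform edge effects.
    """
    filtered = band_filter(epoch, band) if band is not None else epoch
    analytic = signal.hilbert(filtered.data, axis=1)
    amplitude = np.abs(analytic)
    phases = np.angle(analytic)
    trim = int(_PLI_EDGE_FRACTION * phases.shape[1])
    if trim:
        phases = phases[:, trim:-trim]
        amplitude = amplitude[:, trim:-trim]
    diff = phases[:, None, :] - phases[None, :, :]
    values = np.abs(np.sign(np.sin(diff)).mean(axis=2))
    dead = amplitude.max(axis=1) == 0
    values[dead, :] = np.nan
    values[:, dead] = np.nan
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix("pli", band or "unfiltered", values, epoch.channel_names)


def _welch_spectra(data: np.ndarray, fs: float, nperseg: int,
                   noverlap: int) -> Tuple[np.ndarray, np.ndarray]:
    """Windowed segment spectra for Welch cross-spectral estimation.

    Returns ``(freqs, X)`` with ``X`` of shape (channels, segments,
    frequencies); segments are mean-detrended and Hamming-windowed.
    """
    step = nperseg - noverlap
    n = data.shape[1]
    n_seg = 1 + (n - nperseg) // step if n >= nperseg else 0
    if n_seg < 2:
        raise ValueError(
            "magnitude-squared coherence needs at least 2 Welch segments "
            f"(got {n_seg}); shorten the window or reduce the overlap"
        )
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    segments = data[:, idx]  # (ch, seg, nperseg)
    segments = segments - segments.mean(axis=2, keepdims=True)
    window = signal.get_window("hamming", nperseg)
    X = np.fft.rfft(segments * window[None, None, :], axis=2)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, X


def msc(epoch: Epoch, band: str = "full", window_seconds: float = 1.0,
        overlap_fraction: float = 0.5) -> ConnectivityMatrix:
    """Magnitude-squared coherence averaged over the in-band Welch bins."""
    nperseg = int(round(window_seconds * epoch.fs))
    noverlap = int(round(overlap_fraction * nperseg))
    freqs, X = _welch_spectra(epoch.data, epoch.fs, nperseg, noverlap)
    low, high = band_interval(band)
    mask = (freqs >= low) & (freqs < high)
    if not mask.any():
        raise ValueError(f"band {band!r} contains no Welch bins")
    Xb = X[:, :, mask]
    sxy = np.einsum("asf,bsf->abf", Xb, Xb.conj())  # averaged over segments up to 1/n
    sxx = np.einsum("asf,asf->af", Xb, Xb.conj()).real
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = (np.abs(sxy) ** 2) / (sxx[:, None, :] * sxx[None, :, :])
    values = np.nanmean(coh, axis=2) if np.isnan(coh).any() else coh.mean(axis=2)
    np.fill_diagonal(values, 1.0)
    return ConnectivityMatrix("msc", band, values, epoch.channel_names)


def vectorize_connectivity(cm: ConnectivityMatrix) -> pd.Series:
    """Strict upper triangle in row-major channel order, as named features.

    A 16-channel matrix becomes 120 entries named
    ``{measure}_{band}__{chA}-{chB}``.
    """
    n = len(cm.channel_names)
    iu = np.triu_indices(n, k=1)
    names = [
        f"{cm.measure}_{cm.band}__{cm.channel_names[i]}-{cm.channel_names[j]}"
        for i, j in zip(*iu)
    ]
    return pd.Series(cm.values[iu], index=names)


def connectivity_feature_table(
    epochs: Iterable[Epoch],
    measures: Sequence[str] = ("pearson", "pli", "msc"),
    bands: Sequence[str] = CONNECTIVITY_BAND_ORDER,
    window_seconds: float = 1.0,
    overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Connectivity features for a collection of epochs.

    Pearson and PLI are computed on band-filtered signals per band; MSC
    selects in-band bins of the broadband Welch cross-spectra.  Default
    census: 3 measures x 6 bands x 120 pairs = 2160 features per epoch.
    """
    unknown = set(measures) - {"pearson", "pli", "msc"}
    if unknown:
        raise ValueError(f"unknown connectivity measures: {sorted(unknown)}")
    rows: List[pd.Series] = []
    keys: List[Tuple[str, int]] = []
    for epoch in epochs:
        parts: List[pd.Series] = []
        for band in bands:
            filtered = band_filter(epoch, band) if (
                "pearson" in measures or "pli" in measures
            ) else None
            if "pearson" in measures:
                cm = pearson_connectivity(filtered)
                cm.band = band
                parts.append(vectorize_connectivity(cm))
            if "pli" in measures:
                cm = pli(filtered)
                cm.band = band
                parts.append(vectorize_connectivity(cm))
            if "msc" in measures:
                parts.append(vectorize_connectivity(
                    msc(epoch, band, window_seconds, overlap_fraction)
                ))
        rows.append(pd.concat(parts))
        keys.append((epoch.subject_id, epoch.epoch_index))
    index = pd.MultiIndex.from_tuples(keys, names=["subject_id", "epoch_index"])
    return pd.DataFrame(rows, index=index)
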