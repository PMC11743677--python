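"""Spectral EEG features: band-power ratios, spectral entropy, asymmetry.

All features derive from Welch power spectral density estimates of each
epoch.  Per channel the module emits

* five band-power ratios quantifying spectral slowing:
  ``ratio1 = delta/alpha``, ``ratio2 = theta/alpha``,
  ``ratio3 = delta/(alpha+beta)``, ``ratio4 = theta/(alpha+beta)``,
  ``ratio5 = (delta+theta)/(alpha+beta+gamma)``;
* the Shannon entropy of the normalized in-band PSD samples (PSDE),
  ``E = -sum p_i ln p_i`` with ``p_i`` the in-band density values
  normalized to sum 1, for each of the five bands;

and per homologous left/right channel pair the interhemispheric
asymmetry ``IA = log10 P_left - log10 P_right`` in each band.

Ratios, PSDE and IA are all invariant to an overall amplitude rescaling
of the signal.  Degenerate cases (zero band power) yield NaN ("feature
missing") rather than infinities, so downstream feature selection stays
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BANDS, BAND_NAMES
from .preprocessing import Epoch

__all__ = [
    "HOMOLOGOUS_PAIRS",
    "PSDEstimate",
    "BandPowerSet",
    "welch_psd",
    "band_power",
    "band_power_set",
    "psd_ratios",
    "psd_entropy",
    "interhemispheric_asymmetry",
    "spectral_feature_table",
]

#: Left/right homologous channel pairs of the 16-channel 10-20 montage.
HOMOLOGOUS_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("F3", "F4"), ("C3", "C4"), ("P3", "P4"),
    ("O1", "O2"), ("F7", "F8"), ("T3", "T4"), ("T5", "T6"),
)

RATIO_NAMES = ("ratio1", "ratio2", "ratio3", "ratio4", "ratio5")


@dataclass
class PSDEstimate:
    """One-sided Welch PSD per channel (density in µV²/Hz)."""

    frequencies: np.ndarray  # uniform ascending grid, Hz
    density: np.ndarray  # (channels x frequencies), >= 0
    channel_names: Sequence[str]

    def __post_init__(self) -> None:
        if self.density.shape != (len(self.channel_names), self.frequencies.size):
            raise ValueError("density must be (channels x frequencies)")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class BandPowerSet:
    """Per-channel power in each analysis band (rectangle-rule integrals)."""

    powers: Dict[str, np.ndarray]  # band -> (channels,)
    channel_names: Sequence[str]

    def per_channel(self, band: str) -> np.ndarray:
        return self.powers[band]


def welch_psd(epoch: Epoch, window_seconds: float = 1.0,
              overlap_fraction: float = 0.5) -> PSDEstimate:
    """Welch PSD of every channel with a Hamming window.

    Defaults (1-s windows, 50% overlap) give three averaged segments per
    2-s epoch and a 1 Hz grid; for whole 20-s signals pass
    ``window_seconds=2`` for a 0.5 Hz grid.
    """
    nperseg = int(round(window_seconds * epoch.fs))
    if nperseg > epoch.n_samples:
        raise ValueError(
            f"Welch window of {window_seconds} s exceeds the "
            f"{epoch.n_samples / epoch.fs:.3f} s epoch"
        )
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    freqs, density = signal.welch(
        epoch.data, fs=epoch.fs, window="hamming", nperseg=nperseg,
        noverlap=int(round(overlap_fraction * nperseg)), axis=1,
        detrend="constant",
    )
    return PSDEstimate(frequencies=freqs, density=density,
                       channel_names=epoch.channel_names)


def _band_mask(psd: PSDEstimate, band: str | Tuple[float, float]) -> np.ndarray:
    low, high = BANDS[band] if isinstance(band, str) else band
    if high > psd.frequencies[-1] + psd.df:
        raise ValueError(
            f"band [{low}, {high}) Hz extends beyond the PSD grid "
            f"(max {psd.frequencies[-1]:g} Hz)"
        )
    mask = (psd.frequencies >= low) & (psd.frequencies < high)
    if not mask.any():
        raise ValueError(f"band [{low}, {high}) Hz contains no PSD bins")
    return mask


def band_power(psd: PSDEstimate, band: str | Tuple[float, float]) -> np.ndarray:
    """Rectangle-rule integral of the density over a half-open band."""
    mask = _band_mask(psd, band)
    return psd.density[:, mask].sum(axis=1) * psd.df


def band_power_set(psd: PSDEstimate) -> BandPowerSet:
    return BandPowerSet(
        powers={b: band_power(psd, b) for b in BAND_NAMES},
        channel_names=psd.channel_names,
    )


def psd_ratios(bp: BandPowerSet) -> Dict[str, np.ndarray]:
    """The five slow/fast band-power ratios, per channel.

    Zero denominators yield NaN for the affected channel.
    """
    d, t = bp.powers["delta"], bp.powers["theta"]
    a, b, g = bp.powers["alpha"], bp.powers["beta"], bp.powers["gamma"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = {
            "ratio1": d / a,
            "ratio2": t / a,
            "ratio3": d / (a + b),
            "ratio4": t / (a + b),
            "ratio5": (d + t) / (a + b + g),
        }
    return {k: np.where(np.isfinite(v), v, np.nan) for k, v in out.items()}


def psd_entropy(psd: PSDEstimate, band: str | Tuple[float, float]) -> np.ndarray:
    """Shannon entropy (nats) of the normalized in-band PSD samples.

    Bounded by ``[0, ln N]`` for ``N`` in-band bins; an all-zero in-band
    spectrum yields NaN.
    """
    mask = _band_mask(psd, band)
    p = psd.density[:, mask]
    total = p.sum(axis=1, keepdims=True)
    out = np.full(p.shape[0], np.nan)
    ok = total[:, 0] > 0
    if ok.any():
        q = p[ok] / total[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(q > 0, q * np.log(q), 0.0)
        out[ok] = -terms.sum(axis=1)
    return out


def interhemispheric_asymmetry(bp: BandPowerSet, pair: Tuple[str, str],
                               band: str) -> float:
    """``log10(P_left) - log10(P_right)`` for one homologous pair and band.

    Antisymmetric under swapping the pair; NaN if either power is
    nonpositive.
    """
    names = list(bp.channel_names)
    for ch in pair:
        if ch not in names:
            raise ValueError(f"channel {ch!r} not present")
    left = bp.powers[band][names.index(pair[0])]
    right = bp.powers[band][names.index(pair[1])]
    if left <= 0 or right <= 0:
        return float("nan")
    return float(np.log10(left) - np.log10(right))


def spectral_feature_table(
    epochs: Iterable[Epoch],
    window_seconds: float = 1.0,
    overlap_fraction: float = 0.5,
    pairs: Sequence[Tuple[str, str]] = HOMOLOGOUS_PAIRS,
) -> pd.DataFrame:
    """Spectral features for a collection of epochs.

    Returns a DataFrame indexed by ``(subject_id, epoch_index)`` with,
    for a 16-channel montage, 16x5 ratio + 16x5 PSDE + 8x5 IA = 200
    columns named ``ratio1__C3``, ``psde_alpha__O1``,
    ``ia_delta__F3-F4`` etc.
    """
    rows: List[Dict[str, float]] = []
    keys: List[Tuple[str, int]] = []
    for epoch in epochs:
        psd = welch_psd(epoch, window_seconds, overlap_fraction)
        bp = band_power_set(psd)
        row: Dict[str, float] = {}
        ratios = psd_ratios(bp)
        for rname in RATIO_NAMES:
            for ci, ch in enumerate(epoch.channel_names):
                row[f"{rname}__{ch}"] = float(ratios[rname][ci])
        for band in BAND_NAMES:
            ent = psd_entropy(psd, band)
            for ci, ch in enumerate(epoch.channel_names):
                row[f"psde_{band}__{ch}"] = float(ent[ci])
        for band in BAND_NAMES:
            for left, right in pairs:
                row[f"ia_{band}__{left}-{right}"] = interhemispheric_asymmetry(
                    bp, (left, right), band
                )
        rows.append(row)
        keys.append((epoch.subject_id, epoch.epoch_index))
    index = pd.MultiIndex.from_tuples(keys, names=["subject_id", "epoch_index"])
    return pd.DataFrame(rows, index=index)
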