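"""Synthetic two-group resting-state EEG cohorts.

Generates multichannel EEG recordings for two clinical groups — stable
amnestic MCI (SMCI) and amnestic MCI progressing to Alzheimer's disease
(PMCI) — with controllable group differences along the three axes that
distinguish the groups in clinical resting-state EEG:

* **spectral slowing** — the PMCI profile shifts relative band power from
  fast (alpha/beta) toward slow (delta/theta) rhythms;
* **reduced complexity** — less broadband stochastic content, which lowers
  entropy-type measures;
* **functional disconnection** — weaker inter-channel phase coupling,
  which lowers phase-synchronization measures.

Each channel is a sum of (i) band-limited Gaussian noise whose per-band
variances follow the group's relative band-power profile, (ii) a shared
narrowband (alpha-centred) source received by every channel with a fixed
per-channel phase offset, scaled by the group's coupling coefficient, and
(iii) white noise scaled by the group's complexity weight.  Band-limited
Gaussian noise is synthesised in the frequency domain (random-phase
spectral synthesis), which makes Welch band powers directly and exactly
controllable.

Everything is deterministic given the cohort seed: per-subject generators
are seeded from ``(config.seed, subject_index)`` via NumPy seed sequences,
so cohorts regenerate bit-identically and individual subjects can be
re-drawn in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence

import numpy as np

from .bands import BANDS, FULL_BAND

__all__ = [
    "CHANNELS_1020",
    "GROUPS",
    "GroupProfile",
    "CohortConfig",
    "EEGRecording",
    "generate_subject",
    "generate_cohort",
]

#: The 16-channel 10-20 montage used throughout (left/right homologous pairs
#: adjacent: Fp1-Fp2, F3-F4, C3-C4, P3-P4, O1-O2, F7-F8, T3-T4, T5-T6).
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
)

GROUPS = ("SMCI", "PMCI")

#: Band (Hz) of the shared coupling source: the alpha band, the dominant
#: coherent rhythm of eyes-closed resting EEG.  Spanning the whole band
#: (rather than a narrow peak) injects phase coupling without sharpening
#: the in-band spectral shape of the more-connected group.
_COMMON_SOURCE_BAND = (7.5, 13.5)

#: Amplitude fraction of the shared source at full coupling; keeps the
#: coherent part from dominating single-channel dynamics even when
#: ``connectivity_strength`` is 1.
_COMMON_MIX_SCALE = 0.6

#: Root-mean-square amplitude of the oscillatory part, in µV.  Absolute
#: scale is irrelevant to every downstream feature (ratios, entropies and
#: connectivity are scale-free); 30 µV is a typical resting scalp EEG RMS.
_RMS_UV = 30.0


@dataclass(frozen=True)
class GroupProfile:
    """Generator knobs for one clinical group.

    Parameters
    ----------
    band_power
        Relative power per band (delta..gamma); nonnegative, sums to 1.
    connectivity_strength
        Coupling coefficient in [0, 1]: the mixing weight of the shared
        narrowband source relative to channel-specific rhythms.
    complexity_noise
        Broadband white-noise mixing weight in [0, 1]; higher values make
        signals more irregular (higher entropies).
    """

    band_power: Dict[str, float]
    connectivity_strength: float
    complexity_noise: float

    def validate(self) -> None:
        missing = set(BANDS) - set(self.band_power)
        if missing:
            raise ValueError(f"band_power missing bands: {sorted(missing)}")
        weights = np.array([self.band_power[b] for b in BANDS], float)
        if not np.all(np.isfinite(weights)) or np.any(weights < 0):
            raise ValueError("band powers must be finite and nonnegative")
        if not math.isclose(weights.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(f"band powers must sum to 1 (got {weights.sum():.6f})")
        for name in ("connectivity_strength", "complexity_noise"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")


def _default_smci() -> GroupProfile:
    return GroupProfile(
        band_power={"delta": 0.20, "theta": 0.15, "alpha": 0.35,
                    "beta": 0.20, "gamma": 0.10},
        connectivity_strength=0.55,
        complexity_noise=0.60,
    )


def _default_pmci() -> GroupProfile:
    # Slowed spectrum, weaker coupling, less broadband irregularity.
    return GroupProfile(
        band_power={"delta": 0.30, "theta": 0.21, "alpha": 0.24,
                    "beta": 0.16, "gamma": 0.09},
        connectivity_strength=0.30,
        complexity_noise=0.30,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic two-group cohort.

    Defaults mirror the clinical study setting this generator emulates:
    65 stable and 42 progressing subjects, 16 channels of the 10-20
    system at 500 Hz, one artifact-light 20-s segment per subject.
    """

    n_smci: int = 65
    n_pmci: int = 42
    channel_names: Sequence[str] = CHANNELS_1020
    fs: float = 500.0
    duration: float = 20.0
    profiles: Dict[str, GroupProfile] = field(
        default_factory=lambda: {"SMCI": _default_smci(), "PMCI": _default_pmci()}
    )
    seed: int = 0

    # -- preset regimes -------------------------------------------------
    @classmethod
    def null(cls, seed: int = 0, **kw) -> "CohortConfig":
        """Null cohort: both groups share the SMCI profile (no effect)."""
        p = _default_smci()
        return cls(profiles={"SMCI": p, "PMCI": p}, seed=seed, **kw)

    @classmethod
    def strong_effect(cls, seed: int = 0, **kw) -> "CohortConfig":
        """Clearly separated profiles, for effect-recovery exercises."""
        smci = GroupProfile(
            band_power={"delta": 0.14, "theta": 0.12, "alpha": 0.42,
                        "beta": 0.22, "gamma": 0.10},
            connectivity_strength=0.70,
            complexity_noise=0.80,
        )
        pmci = GroupProfile(
            band_power={"delta": 0.40, "theta": 0.25, "alpha": 0.14,
                        "beta": 0.13, "gamma": 0.08},
            connectivity_strength=0.15,
            complexity_noise=0.15,
        )
        return cls(profiles={"SMCI": smci, "PMCI": pmci}, seed=seed, **kw)

    def with_sizes(self, n_smci: int, n_pmci: int) -> "CohortConfig":
        return replace(self, n_smci=n_smci, n_pmci=n_pmci)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def validate(self) -> None:
        if self.n_smci < 1 or self.n_pmci < 1:
            raise ValueError("group sizes must be >= 1")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"fs must be positive and finite, got {self.fs!r}")
        if not (np.isfinite(self.duration) and self.duration > 0):
            raise ValueError("duration must be positive and finite")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"duration*fs must be an integer sample count, got {n}")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if len(self.channel_names) < 2:
            raise ValueError("need at least 2 channels")
        for g in GROUPS:
            if g not in self.profiles:
                raise ValueError(f"missing profile for group {g}")
            self.profiles[g].validate()


@dataclass
class EEGRecording:
    """A multichannel EEG recording in µV.

    ``data`` is a (channels x samples) float array; row order matches
    ``channel_names``.
    """

    subject_id: str
    group: str  # 'SMCI', 'PMCI' or 'unknown'
    channel_names: Sequence[str]
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{len(self.channel_names)} channel names but "
                f"{self.data.shape[0]} data rows"
            )
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError("fs must be positive and finite")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("all samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _band_limited_noise(
    rng: np.random.Generator, n_channels: int, n: int, fs: float,
    low: float, high: float, flat: bool = False,
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to ``[low, high)`` Hz.

    Random-phase spectral synthesis: i.i.d. complex-Gaussian rFFT
    coefficients inside the band, zero outside, with a gentle 1/sqrt(f)
    in-band 1/f slope for realism (``flat=True`` disables the slope);
    normalized to unit variance per channel.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= low) & (freqs < high)
    if not np.any(mask):
        return np.zeros((n_channels, n))
    spec = np.zeros((n_channels, freqs.size), dtype=np.complex128)
    k = int(mask.sum())
    amp = 1.0 if flat else 1.0 / np.maximum(freqs[mask], 0.5)
    spec[:, mask] = (
        rng.standard_normal((n_channels, k)) + 1j * rng.standard_normal((n_channels, k))
    ) * amp
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _analytic_narrowband(rng: np.random.Generator, n: int, fs: float,
                         low: float, high: float) -> np.ndarray:
    """Complex analytic narrowband source (unit variance of its real part)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= low) & (freqs < high)
    spec = np.zeros(freqs.size, dtype=np.complex128)
    k = int(mask.sum())
    spec[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    # one-sided spectrum -> analytic signal via inverse FFT on full grid
    full = np.zeros(n, dtype=np.complex128)
    full[: freqs.size] = spec
    z = np.fft.ifft(full * 2.0, n=n)
    sd = z.real.std()
    if sd == 0:
        return z
    return z / sd


def generate_subject(config: CohortConfig, group: str, subject_seed: int) -> EEGRecording:
    """Generate one subject's recording, deterministically.

    The subject-level random stream is derived from
    ``(config.seed, subject_seed)``; calling twice with the same triple
    yields bit-identical data.
    """
    config.validate()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    profile = config.profiles[group]
    n = config.n_samples
    n_ch = len(config.channel_names)
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), int(subject_seed))))

    # band-limited oscillatory mixture with the group's band-power profile
    osc = np.zeros((n_ch, n))
    for band, (low, high) in BANDS.items():
        w = profile.band_power[band]
        if w <= 0:
            continue
        osc += math.sqrt(w) * _band_limited_noise(rng, n_ch, n, config.fs, low, high)

    # shared alpha-band source: identical waveform received with a fixed
    # random per-channel phase offset.  Uniform phases over the full circle
    # keep the channel-mean of the shared part near zero, so the common
    # average reference in preprocessing removes almost none of it.
    rho = _COMMON_MIX_SCALE * profile.connectivity_strength
    z = _analytic_narrowband(rng, n, config.fs, *_COMMON_SOURCE_BAND)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)
    common = (z[None, :] * np.exp(1j * phases[:, None])).real

    mix = (1.0 - rho) * osc + rho * common
    mix_sd = mix.std(axis=1, keepdims=True)
    mix_sd[mix_sd == 0] = 1.0
    mix /= mix_sd

    # broadband irregularity: flat-spectrum noise confined to the analysis
    # band (so preprocessing removes the same variance from every profile),
    # added on top of the unit-variance rhythms — more irregular profiles
    # are also slightly higher-power, as broadband-noisy EEG is
    eta = profile.complexity_noise
    white = _band_limited_noise(rng, n_ch, n, config.fs, *FULL_BAND, flat=True)
    x = mix + eta * white

    # per-channel amplitude heterogeneity (scale-free features ignore it)
    gains = rng.uniform(0.8, 1.25, size=(n_ch, 1))
    x *= _RMS_UV * gains

    return EEGRecording(
        subject_id="anon",
        group=group,
        channel_names=tuple(config.channel_names),
        fs=config.fs,
        data=x,
    )


def _subject_seed(config_seed: int, index: int) -> int:
    """Reproducible per-subject seed from the cohort seed and subject index."""
    ss = np.random.SeedSequence((int(config_seed), int(index)))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(config: CohortConfig) -> List[EEGRecording]:
    """Generate the full cohort: SMCI subjects first, then PMCI.

    Subject IDs are ``SMCI001..`` / ``PMCI001..``; per-subject seeds are
    derived from ``config.seed`` and the global subject index, so the
    cohort is reproducible and subjects are independent streams.
    """
    config.validate()
    recordings: List[EEGRecording] = []
    index = 0
    for group, n_group in (("SMCI", config.n_smci), ("PMCI", config.n_pmci)):
        for i in range(n_group):
            rec = generate_subject(config, group, _subject_seed(config.seed, index))
            rec.subject_id = f"{group}{i + 1:03d}"
            recordings.append(rec)
            index += 1
    return recordings
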