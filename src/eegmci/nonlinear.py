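"""Nonlinear (complexity) EEG features.

Per channel and epoch the module computes

* multiscale permutation entropy (PE), approximate entropy (AE) and
  sample entropy (SE) over coarse-graining scales 1-10 (non-overlapping
  block means), with the AE/SE tolerance fixed from the scale-1 standard
  deviation so values are comparable across scales;
* Lempel-Ziv complexity (LZ76 phrase counting after binarization at the
  signal mean), reported in normalized form ``c(n) log2(n) / n``;
* the rescaled-range (R/S) Hurst exponent;
* the median distance from the centroid of the 3-D delay-embedded
  trajectory (phase-space reconstruction with the delay chosen from the
  autocorrelation function) — a compact summary of the spread of the
  reconstructed attractor.

All five entropy-type quantities increase with signal irregularity.
Degenerate inputs (zero variance, too-short series, no template matches)
yield the documented conventions (0 for entropies of constants, NaN for
undefined estimates) instead of raising.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .preprocessing import Epoch

__all__ = [
    "coarse_grain",
    "permutation_entropy",
    "approximate_entropy",
    "sample_entropy",
    "lempel_ziv",
    "lz76_phrase_count",
    "hurst_exponent",
    "psr_lag",
    "m_dcpsr",
    "multiscale",
    "nonlinear_feature_table",
]

DEFAULT_SCALES: Tuple[int, ...] = tuple(range(1, 11))


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping block means of length ``scale`` (scale 1 = identity)."""
    x = np.asarray(x, dtype=np.float64)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if scale > x.size:
        raise ValueError(f"scale {scale} exceeds signal length {x.size}")
    n_blocks = x.size // scale
    return x[: n_blocks * scale].reshape(n_blocks, scale).mean(axis=1)


def _delay_embed(x: np.ndarray, m: int, delay: int) -> np.ndarray:
    """Matrix of delay vectors ``(x_t, x_{t+d}, ..., x_{t+(m-1)d})``."""
    n_vec = x.size - (m - 1) * delay
    if n_vec < 1:
        return np.empty((0, m))
    idx = np.arange(n_vec)[:, None] + delay * np.arange(m)[None, :]
    return x[idx]


def permutation_entropy(x: np.ndarray, m: int = 3, delay: int = 1) -> float:
    """Shannon entropy (nats) of the ordinal-pattern distribution.

    Ordinal patterns are ranks of each delay vector (stable sort, so ties
    resolve by order of occurrence); bounded by ``[0, ln m!]``.
    """
    x = np.asarray(x, dtype=np.float64)
    vecs = _delay_embed(x, m, delay)
    if vecs.shape[0] < 2:
        return float("nan")
    patterns = np.argsort(vecs, axis=1, kind="stable")
    # encode each pattern as an integer in factorial-free base m
    codes = (patterns * (m ** np.arange(m))[None, :]).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


_DIST_BLOCK = 512  # row block for chunked Chebyshev distance scans


def _row_counts(templates: np.ndarray, r: float) -> np.ndarray:
    """Per-template count of templates within Chebyshev distance r (self
    included), computed in row blocks to bound memory on long signals."""
    nt = templates.shape[0]
    if nt <= 1500:
        return (cdist(templates, templates, "chebyshev") <= r).sum(axis=1)
    counts = np.empty(nt, dtype=np.int64)
    for i in range(0, nt, _DIST_BLOCK):
        d = cdist(templates[i : i + _DIST_BLOCK], templates, "chebyshev")
        counts[i : i + _DIST_BLOCK] = (d <= r).sum(axis=1)
    return counts


def approximate_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2,
                        r: Optional[float] = None) -> float:
    """Approximate entropy ApEn(m, r) with self-matches included.

    ``r`` defaults to ``r_frac`` times the standard deviation of ``x``;
    pass ``r`` explicitly to fix the tolerance (multiscale convention).
    Constant signals return 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < m + 2:
        return float("nan")
    if np.ptp(x) == 0:
        return 0.0
    if r is None:
        r = r_frac * x.std()
    phi = []
    for mm in (m, m + 1):
        templates = _delay_embed(x, mm, 1)
        c = _row_counts(templates, r) / templates.shape[0]
        phi.append(np.log(c).mean())
    return float(phi[0] - phi[1])


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2,
                   r: Optional[float] = None) -> float:
    """Sample entropy ``-ln(A/B)`` with self-matches excluded.

    ``A`` and ``B`` count template pairs within tolerance at lengths
    ``m+1`` and ``m`` over the same ``n - m`` templates.  Constant
    signals return 0; zero ``A`` or ``B`` yields NaN (undefined).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < m + 2:
        return float("nan")
    if np.ptp(x) == 0:
        return 0.0
    if r is None:
        r = r_frac * x.std()
    n_templ = x.size - m  # same template count at both lengths
    counts = []
    for mm in (m, m + 1):
        templates = _delay_embed(x, mm, 1)[:n_templ]
        total = int(_row_counts(templates, r).sum())
        counts.append((total - n_templ) // 2)  # exclude self, unordered pairs
    b, a = counts
    if a == 0 or b == 0:
        return float("nan")
    return float(-math.log(a / b))


def _ae_se_pair(x: np.ndarray, m: int, r: float) -> Tuple[float, float]:
    """(AE, SE) sharing the two distance matrices — used by the bulk path."""
    if x.size < m + 2:
        return float("nan"), float("nan")
    if np.ptp(x) == 0:
        return 0.0, 0.0
    n_templ = x.size - m
    phi = []
    pair_counts = []
    for mm in (m, m + 1):
        templates = _delay_embed(x, mm, 1)
        nt = templates.shape[0]
        row_counts = np.empty(nt, dtype=np.int64)
        sub_sum = 0
        block = nt if nt <= 1500 else _DIST_BLOCK
        for i in range(0, nt, block):
            within = cdist(templates[i : i + block], templates, "chebyshev") <= r
            row_counts[i : i + block] = within.sum(axis=1)
            top = min(i + block, n_templ) - i
            if top > 0:
                sub_sum += int(within[:top, :n_templ].sum())
        phi.append(np.log(row_counts / nt).mean())
        pair_counts.append((sub_sum - n_templ) // 2)
    ae = float(phi[0] - phi[1])
    a, b = pair_counts[1], pair_counts[0]
    se = float("nan") if (a == 0 or b == 0) else float(-math.log(a / b))
    return ae, se


def lz76_phrase_count(bits: np.ndarray) -> int:
    """LZ76 phrase count of a binary sequence (Kaspar-Schuster scan)."""
    s = np.asarray(bits).astype(np.int8)
    n = s.size
    if n == 0:
        raise ValueError("empty sequence")
    i, k, l = 0, 1, 1
    c, k_max = 1, 1
    while True:
        if l + k - 1 >= n:
            c += 1
            break
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def lempel_ziv(x: np.ndarray, normalized: bool = True) -> float:
    """Lempel-Ziv complexity after binarizing at the signal mean.

    ``s_i = 1`` if ``x_i > mean(x)`` else 0; returns the LZ76 phrase
    count ``c(n)``, normalized (default) as ``c(n) log2(n) / n`` so that
    random sequences score near 1.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    bits = (x > x.mean()).astype(np.int8)
    c = lz76_phrase_count(bits)
    if not normalized:
        return float(c)
    return float(c * math.log2(x.size) / x.size)


def hurst_exponent(x: np.ndarray, min_block: int = 8) -> float:
    """Rescaled-range (R/S) Hurst exponent.

    Mean R/S over non-overlapping blocks at dyadic sizes from
    ``min_block`` to ``n/2``; the estimate is the slope of the log-log
    regression of mean R/S on block size.  ~0.5 for i.i.d. noise, near 1
    for integrated noise; invariant to affine rescaling of the signal.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 8 * min_block:
        return float("nan")
    if np.ptp(x) == 0:
        return float("nan")
    sizes = []
    size = min_block
    while size <= x.size // 2:
        sizes.append(size)
        size *= 2
    log_rs, log_sizes = [], []
    for s in sizes:
        blocks = x[: (x.size // s) * s].reshape(-1, s)
        dev = blocks - blocks.mean(axis=1, keepdims=True)
        cum = dev.cumsum(axis=1)
        rng = cum.max(axis=1) - cum.min(axis=1)
        sd = blocks.std(axis=1)
        ok = sd > 0
        if not ok.any():
            continue
        log_rs.append(math.log((rng[ok] / sd[ok]).mean()))
        log_sizes.append(math.log(s))
    if len(log_rs) < 2:
        return float("nan")
    slope = np.polyfit(log_sizes, log_rs, 1)[0]
    return float(slope)


def psr_lag(x: np.ndarray, m: int = 3) -> int:
    """Embedding delay from the sample autocorrelation function.

    The delay is the smallest lag at which the autocorrelation first
    drops to zero or below, searched up to ``n/3``; if it never crosses
    zero there, the smallest lag where it falls to ``1/e`` is used.  The
    result is capped so that at least one m-dimensional delay vector
    exists, with a floor of 1.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    xc = x - x.mean()
    denom = (xc * xc).sum()
    cap = max(1, (n - 1) // (m - 1))
    if denom == 0:
        return 1
    full = np.correlate(xc, xc, mode="full")[n - 1 :]
    acf = full / denom
    limit = max(2, n // 3)
    zero_cross = np.nonzero(acf[1:limit] <= 0)[0]
    if zero_cross.size:
        return min(int(zero_cross[0]) + 1, cap)
    below_e = np.nonzero(acf[1:] <= 1.0 / math.e)[0]
    if below_e.size:
        return min(int(below_e[0]) + 1, cap)
    return 1


def m_dcpsr(x: np.ndarray, m: int = 3, tau: Optional[int] = None) -> float:
    """Median distance from the centroid of the reconstructed phase space.

    The signal is delay-embedded in ``m`` dimensions with delay ``tau``
    (chosen by :func:`psr_lag` when not given); the statistic is the
    median Euclidean distance of the trajectory points from their
    centroid.  Absolutely homogeneous (``f(a x) = a f(x)``) and
    translation invariant; 0 for constant signals.
    """
    x = np.asarray(x, dtype=np.float64)
    if tau is None:
        tau = psr_lag(x, m)
    if x.size < (m - 1) * tau + 2:
        return float("nan")
    points = _delay_embed(x, m, tau)
    centroid = points.mean(axis=0)
    dist = np.linalg.norm(points - centroid, axis=1)
    return float(np.median(dist))


def multiscale(
    feature_op: Callable[..., float],
    x: np.ndarray,
    scales: Sequence[int] = DEFAULT_SCALES,
    **kwargs,
) -> np.ndarray:
    """Apply a feature to coarse-grained versions of ``x`` at each scale.

    For AE/SE the tolerance ``r`` is fixed from the standard deviation
    of the original (scale-1) series unless supplied explicitly, so that
    values are comparable across scales.  Per-scale failures yield NaN
    without affecting other scales.
    """
    x = np.asarray(x, dtype=np.float64)
    if feature_op in (approximate_entropy, sample_entropy) and "r" not in kwargs:
        kwargs = {**kwargs, "r": kwargs.pop("r_frac", 0.2) * x.std()}
    values = []
    for s in scales:
        try:
            values.append(float(feature_op(coarse_grain(x, s), **kwargs)))
        except (ValueError, FloatingPointError):
            values.append(float("nan"))
    return np.asarray(values)


_SINGLE_SCALE = ("lz", "hurst", "mdcpsr")


def nonlinear_feature_table(
    epochs: Iterable[Epoch],
    scales: Sequence[int] = DEFAULT_SCALES,
    features: Sequence[str] = ("pe", "ae", "se", "lz", "hurst", "mdcpsr"),
    pe_m: int = 3,
    pe_delay: int = 1,
    ent_m: int = 2,
    r_frac: float = 0.2,
) -> pd.DataFrame:
    """Nonlinear features for a collection of epochs.

    Columns follow ``pe_s{scale}__{channel}`` for the multiscale
    entropies and ``lz__{channel}`` etc. for the single-scale measures;
    the default census on a 16-channel montage is 3x10x16 + 3x16 = 528
    features per epoch.
    """
    unknown = set(features) - {"pe", "ae", "se", "lz", "hurst", "mdcpsr"}
    if unknown:
        raise ValueError(f"unknown nonlinear features: {sorted(unknown)}")
    rows: List[Dict[str, float]] = []
    keys: List[Tuple[str, int]] = []
    want_ae = "ae" in features
    want_se = "se" in features
    for epoch in epochs:
        row: Dict[str, float] = {}
        for ci, ch in enumerate(epoch.channel_names):
            x = epoch.data[ci]
            if "pe" in features:
                for s in scales:
                    row[f"pe_s{s}__{ch}"] = permutation_entropy(
                        coarse_grain(x, s), pe_m, pe_delay
                    )
            if want_ae or want_se:
                r = r_frac * x.std()
                for s in scales:
                    ae, se = _ae_se_pair(coarse_grain(x, s), ent_m, r)
                    if want_ae:
                        row[f"ae_s{s}__{ch}"] = ae
                    if want_se:
                        row[f"se_s{s}__{ch}"] = se
            if "lz" in features:
                row[f"lz__{ch}"] = lempel_ziv(x)
            if "hurst" in features:
                row[f"hurst__{ch}"] = hurst_exponent(x)
            if "mdcpsr" in features:
                row[f"mdcpsr__{ch}"] = m_dcpsr(x)
        rows.append(row)
        keys.append((epoch.subject_id, epoch.epoch_index))
    index = pd.MultiIndex.from_tuples(keys, names=["subject_id", "epoch_index"])
    return pd.DataFrame(rows, index=index)
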