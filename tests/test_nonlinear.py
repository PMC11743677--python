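"""Nonlinear features: entropies, LZ76, Hurst, phase-space statistic."""

import math

import numpy as np
import pytest

from eegmci.nonlinear import (
    approximate_entropy,
    coarse_grain,
    hurst_exponent,
    lempel_ziv,
    lz76_phrase_count,
    m_dcpsr,
    multiscale,
    nonlinear_feature_table,
    permutation_entropy,
    psr_lag,
    sample_entropy,
)
from .oracles import apen_oracle, lz76_oracle, mdcpsr_oracle, pe_oracle, sampen_oracle


# ---------------------------------------------------------------- coarse grain

def test_coarse_grain_block_means():
    np.testing.assert_allclose(coarse_grain([1, 2, 3, 4], 2), [1.5, 3.5])
    np.testing.assert_allclose(coarse_grain([1, 2, 3, 4, 5], 2), [1.5, 3.5])
    x = np.arange(10.0)
    np.testing.assert_array_equal(coarse_grain(x, 1), x)
    np.testing.assert_allclose(coarse_grain(np.full(30, 2.5), 7), np.full(4, 2.5))
    with pytest.raises(ValueError):
        coarse_grain([1.0, 2.0], 3)


# ------------------------------------------------------------------- entropies

def test_pe_monotone_series_is_zero():
    assert permutation_entropy(np.arange(100.0), m=3) == pytest.approx(0.0)


def test_pe_converges_to_ln6_for_noise(rng):
    x = rng.standard_normal(5000)
    assert permutation_entropy(x, m=3) == pytest.approx(np.log(6), rel=0.05)


def test_pe_bounded_by_ln_m_factorial(rng):
    for m in (2, 3, 4):
        pe = permutation_entropy(rng.standard_normal(300), m=m)
        assert 0 <= pe <= np.log(math.factorial(m)) + 1e-12


def test_constant_signal_conventions():
    c = np.full(200, 3.0)
    assert approximate_entropy(c) == 0.0
    assert sample_entropy(c) == 0.0
    assert np.isnan(hurst_exponent(c))
    assert m_dcpsr(c) == 0.0


def test_periodic_signal_matches_oracles():
    x = np.tile([1.0, 2.0], 50)
    r = 0.2 * x.std()
    assert approximate_entropy(x, 2, r=r) == pytest.approx(
        apen_oracle(x, 2, r=r), abs=1e-12
    )
    assert sample_entropy(x, 2, r=r) == pytest.approx(
        sampen_oracle(x, 2, r=r), abs=1e-12
    )


@pytest.mark.parametrize("seed", range(10))
def test_entropy_oracle_equivalence_random_signals(seed):
    """Vectorized PE/AE/SE match naive double-loop oracles exactly."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, 200))
    x = rng.standard_normal(n)
    r = 0.2 * x.std()
    assert permutation_entropy(x, 3, 1) == pytest.approx(pe_oracle(x, 3, 1), abs=1e-10)
    assert approximate_entropy(x, 2, r=r) == pytest.approx(
        apen_oracle(x, 2, r=r), abs=1e-10
    )
    se, se_o = sample_entropy(x, 2, r=r), sampen_oracle(x, 2, r=r)
    if np.isnan(se_o):
        assert np.isnan(se)
    else:
        assert se == pytest.approx(se_o, abs=1e-10)


def test_complexity_ordering_noise_above_sine(rng):
    """White noise is more irregular than a sine of equal length."""
    t = np.arange(500) / 250.0
    wins = {"pe": 0, "ae": 0, "se": 0, "lz": 0}
    n_draws = 20
    for _ in range(n_draws):
        noise = rng.standard_normal(500)
        sine = np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))
        wins["pe"] += permutation_entropy(noise) > permutation_entropy(sine)
        wins["ae"] += approximate_entropy(noise) > approximate_entropy(sine)
        wins["se"] += sample_entropy(noise) > sample_entropy(sine)
        wins["lz"] += lempel_ziv(noise) > lempel_ziv(sine)
    for name, count in wins.items():
        assert count >= 0.9 * n_draws, name


def test_se_noise_above_lowpassed_noise(rng):
    from scipy import signal as sp_signal

    b = sp_signal.firwin(101, 5.0, fs=250.0)
    higher = 0
    for _ in range(10):
        x = rng.standard_normal(500)
        smooth = sp_signal.filtfilt(b, [1.0], x)
        higher += sample_entropy(x) > sample_entropy(smooth)
    assert higher >= 9


# ------------------------------------------------------------------------- LZ

def test_lz76_hand_traces():
    # 0^n: '0' is the first component, the copyable tail the terminal one
    assert lz76_phrase_count(np.zeros(10, dtype=int)) == 2
    # 0101010101 parses as 0 | 1 | 01010101
    assert lz76_phrase_count(np.array([0, 1] * 5)) == 3
    assert lempel_ziv(np.full(10, 7.0), normalized=False) == 2.0


@pytest.mark.parametrize("seed", range(10))
def test_lz76_oracle_equivalence(seed):
    rng = np.random.default_rng(100 + seed)
    bits = rng.integers(0, 2, int(rng.integers(20, 200)))
    assert lz76_phrase_count(bits) == lz76_oracle(bits)


def test_normalized_lz_near_one_for_random(rng):
    x = rng.standard_normal(10000)
    assert 0.8 <= lempel_ziv(x) <= 1.2


# ---------------------------------------------------------------------- Hurst

def test_hurst_of_white_noise(rng):
    estimates = [hurst_exponent(rng.standard_normal(4096)) for _ in range(20)]
    assert 0.4 <= np.mean(estimates) <= 0.6


def test_hurst_of_integrated_noise(rng):
    estimates = [
        hurst_exponent(np.cumsum(rng.standard_normal(4096))) for _ in range(10)
    ]
    assert 0.85 <= np.mean(estimates) <= 1.05


def test_hurst_affine_invariance(rng):
    x = rng.standard_normal(1024)
    assert hurst_exponent(5.0 * x + 3.0) == pytest.approx(hurst_exponent(x), abs=1e-9)


# -------------------------------------------------------------------- M-DCPSR

def test_mdcpsr_homogeneity_and_shift_invariance(rng):
    x = rng.standard_normal(600)
    v = m_dcpsr(x)
    assert m_dcpsr(4.0 * x) == pytest.approx(4.0 * v, rel=1e-9)
    assert m_dcpsr(x + 11.0) == pytest.approx(v, rel=1e-6)


def test_mdcpsr_sine_matches_independent_reimplementation():
    t = np.arange(500) / 250.0
    x = np.sin(2 * np.pi * 10 * t)
    assert m_dcpsr(x) == pytest.approx(mdcpsr_oracle(x), abs=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_mdcpsr_oracle_equivalence_random(seed):
    rng = np.random.default_rng(200 + seed)
    x = rng.standard_normal(int(rng.integers(40, 200)))
    assert m_dcpsr(x) == pytest.approx(mdcpsr_oracle(x), abs=1e-10)


def test_psr_lag_of_slow_oscillation():
    # 2.5 Hz sine at 250 Hz: quarter period = 25 samples -> acf zero there
    t = np.arange(1000) / 250.0
    assert psr_lag(np.sin(2 * np.pi * 2.5 * t)) == pytest.approx(25, abs=1)


# ------------------------------------------------------------------ multiscale

def test_multiscale_scale1_equals_plain(rng):
    x = rng.standard_normal(500)
    ms = multiscale(sample_entropy, x, scales=(1, 2, 5))
    assert ms[0] == pytest.approx(sample_entropy(x), abs=1e-12)
    assert ms.shape == (3,)


def test_multiscale_fixes_tolerance_from_scale1(rng):
    x = rng.standard_normal(400)
    r = 0.2 * x.std()
    ms = multiscale(sample_entropy, x, scales=(3,))
    assert ms[0] == pytest.approx(sample_entropy(coarse_grain(x, 3), r=r), abs=1e-12)


def test_multiscale_se_decreases_for_white_noise(rng):
    diffs = []
    for _ in range(10):
        x = rng.standard_normal(1000)
        ms = multiscale(sample_entropy, x, scales=(1, 10))
        diffs.append(ms[0] - ms[1])
    assert np.mean(diffs) > 0


def test_feature_census(tiny_epochs):
    table = nonlinear_feature_table(tiny_epochs[:2])
    assert table.shape == (2, 528)
    entropies = table.filter(regex=r"^(pe|se)_")
    assert (entropies.stack().dropna() >= -1e-12).all()
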