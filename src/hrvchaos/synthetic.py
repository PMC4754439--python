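"""Synthetic series with known fractal ground truth, plus shuffling surrogates.

Every analysis stage in this package is validated offline against generators
whose scaling behaviour is known in closed form:

* fractional Gaussian noise (fGn) and its cumulative sum, fractional Brownian
  motion (fBm) — monofractal, indexed by the Hurst exponent ``H``;
* the deterministic binomial multifractal cascade, whose generalized Hurst
  exponents are ``h(q) = 1/q - log2(a**q + (1-a)**q) / q``;
* a BPM-like stand-in (baseline + slow oscillation + correlated noise) that
  mimics the range and character of instantaneous heart-rate recordings.

Shuffled surrogates (random permutations) preserve the value distribution
exactly while destroying temporal correlations; they are the baseline against
which correlation-driven multifractality is judged.
"""

from __future__ import annotations

import numpy as np

from .core import DegenerateInputError, HrvChaosError, TimeSeries

__all__ = [
    "FgnEmbeddingError",
    "generate_fgn",
    "generate_fbm",
    "generate_binomial_cascade",
    "generate_bpm_like",
    "shuffle_series",
    "cascade_hurst",
]


class FgnEmbeddingError(HrvChaosError):
    """Circulant embedding of the fGn covariance was not positive semidefinite."""


def _fgn_autocovariance(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Exact fGn autocovariance gamma(k) = 0.5(|k+1|^2H - 2|k|^2H + |k-1|^2H)."""
    k = np.abs(lags.astype(float))
    two_h = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** two_h - 2.0 * k**two_h + np.abs(k - 1) ** two_h)


def generate_fgn(hurst: float, n: int, seed: int) -> TimeSeries:
    """Sample fractional Gaussian noise with exact covariance structure.

    Uses circulant embedding of the autocovariance sequence: the covariance of
    the output is the fGn autocovariance exactly (in distribution), not a
    spectral approximation.  Unit variance, zero mean.

    Raises
    ------
    FgnEmbeddingError
        If the circulant embedding has negative eigenvalues for this ``n``
        (increase ``n``; for H in (0,1) the minimal embedding is provably
        nonnegative, so this is a numerical safeguard).
    """
    if not 0.0 < hurst < 1.0:
        raise HrvChaosError(f"hurst must be in (0, 1), got {hurst}")
    if n < 16:
        raise HrvChaosError(f"n must be >= 16, got {n}")
    m = 2 * n
    gamma = _fgn_autocovariance(hurst, np.arange(n + 1))
    # first row of the circulant: gamma(0..n), then mirrored gamma(n-1..1)
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-8 * lam.max():
        raise FgnEmbeddingError(
            f"circulant embedding not positive semidefinite for n={n} "
            f"(min eigenvalue {lam.min():.3e}); increase n"
        )
    lam = np.clip(lam, 0.0, None)
    rng = np.random.default_rng(seed)
    # complex randomization: real and imaginary parts each N(0, lam/m), so the
    # real part of the FFT has covariance exactly gamma
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam / m) * z).real[:n]
    return TimeSeries(values=x, label=f"fgn(H={hurst}, n={n}, seed={seed})")


def generate_fbm(hurst: float, n: int, seed: int) -> TimeSeries:
    """Fractional Brownian motion: cumulative sum of ``generate_fgn`` output.

    The first value equals the first increment, so ``np.diff`` with the first
    sample prepended recovers the fGn series exactly.
    """
    fgn = generate_fgn(hurst, n, seed)
    return TimeSeries(
        values=np.cumsum(fgn.values), label=f"fbm(H={hurst}, n={n}, seed={seed})"
    )


def generate_binomial_cascade(a: float, n_levels: int) -> TimeSeries:
    """Deterministic binomial multifractal cascade of length ``2**n_levels``.

    ``x[k] = a**ones(k-1) * (1-a)**(n_levels - ones(k-1))`` where ``ones``
    counts set bits in the binary expansion.  The values sum to one; the series
    is the canonical multifractal oracle with closed-form h(q) (see
    :func:`cascade_hurst`).
    """
    if not 0.5 < a < 1.0:
        raise HrvChaosError(f"cascade parameter a must be in (0.5, 1), got {a}")
    if not 8 <= n_levels <= 20:
        raise HrvChaosError(f"n_levels must be in [8, 20], got {n_levels}")
    k = np.arange(2**n_levels, dtype=np.uint64)
    ones = np.bitwise_count(k).astype(float)
    x = a**ones * (1.0 - a) ** (n_levels - ones)
    return TimeSeries(values=x, label=f"cascade(a={a}, levels={n_levels})")


def cascade_hurst(a: float, q: np.ndarray | float) -> np.ndarray | float:
    """Closed-form generalized Hurst exponent of the binomial cascade.

    ``h(q) = 1/q - ln(a**q + (1-a)**q) / (q ln 2)``; at q = 0 the continuous
    limit ``-(ln a + ln(1-a)) / (2 ln 2)`` is used.  Strictly decreasing in q
    for a > 0.5 — the hallmark of multifractality.
    """
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = 1.0 / q - np.log(a**q + (1.0 - a) ** q) / (q * np.log(2.0))
    h = np.where(
        np.abs(q) < 1e-12,
        -(np.log(a) + np.log(1.0 - a)) / (2.0 * np.log(2.0)),
        h,
    )
    return h if h.ndim else float(h)


def generate_bpm_like(
    baseline: float = 75.0,
    osc_amplitude: float = 8.0,
    osc_period: float = 60.0,
    hurst: float = 0.8,
    noise_scale: float = 4.0,
    n: int = 4096,
    seed: int = 0,
) -> TimeSeries:
    """BPM-like series: baseline + slow sinusoid + correlated (fGn) noise.

    A stand-in for instantaneous heart rate, not a physiological model.
    Defaults produce series in roughly the 55-105 BPM range with long-range
    correlated beat-to-beat variability.  ``osc_period`` is in samples.

    Raises
    ------
    DegenerateInputError
        If the chosen parameters yield non-positive BPM values.
    """
    if baseline <= 0:
        raise HrvChaosError(f"baseline must be positive, got {baseline}")
    if n < 400:
        raise HrvChaosError(f"n must be >= 400 for a BPM-like series, got {n}")
    i = np.arange(n, dtype=float)
    x = np.full(n, float(baseline))
    if osc_amplitude != 0.0:
        x += osc_amplitude * np.sin(2.0 * np.pi * i / float(osc_period))
    if noise_scale != 0.0:
        x += noise_scale * generate_fgn(hurst, n, seed).values
    if np.any(x <= 0):
        raise DegenerateInputError(
            "parameters produced non-positive BPM values; reduce amplitude "
            "or noise scale relative to baseline"
        )
    return TimeSeries(values=x, label=f"bpm_like(seed={seed})")


def shuffle_series(series: TimeSeries, seed: int) -> TimeSeries:
    """Uniform random permutation surrogate of ``series``, seeded.

    Preserves the multiset of values exactly (hence mean and variance) while
    destroying temporal ordering.  Callers wanting several surrogates for
    averaging pass distinct seeds.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(series.values)
    return TimeSeries(values=perm, times=None, label=f"{series.label} [shuffled]")
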