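"""Multifractal detrended fluctuation analysis (MF-DFA).

The method quantifies how the fluctuations of a series scale with window
size, separately for every moment order q:

1. integrate the mean-subtracted series into a profile
   ``Y(i) = sum_{k<=i} (x(k) - mean(x))``;
2. split the profile into ``N_s = floor(N/s)`` non-overlapping bins of
   length s and compute, per bin, the mean squared residual ``F2(s, v)``
   around an order-m least-squares polynomial trend;
3. aggregate the bins into the q-th order fluctuation function
   ``F_q(s) = ( mean_v F2(s, v)**(q/2) )**(1/q)`` (log-average limit at
   q = 0);
4. estimate the generalized Hurst exponent h(q) as the slope of
   ``log2 F_q(s)`` on ``log2 s``;
5. Legendre-transform via ``tau(q) = q h(q) - 1`` into the singularity
   spectrum ``alpha = h + q h'``, ``f(alpha) = q (alpha - h) + 1``.

The headline statistic is the spectrum width ``max(alpha) - min(alpha)``: ~0
for a monofractal series, large when small and large fluctuations scale
differently.  Negative q emphasise the bins with the smallest fluctuations,
positive q the largest; h(q) is non-increasing in q up to estimation noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DegenerateInputError, HrvChaosError, TimeSeries

__all__ = [
    "MfdfaConfig",
    "MfdfaResult",
    "compute_profile",
    "local_rms",
    "fluctuation_function",
    "generalized_hurst",
    "tau_from_h",
    "singularity_spectrum",
    "spectrum_width",
    "run_mfdfa",
]

#: |q| below this is treated as the q -> 0 logarithmic-average limit
_Q_ZERO_TOL = 1e-6

#: below this length the scaling regression has too few independent bins
RELIABLE_MIN_LENGTH = 1024


def default_q_grid(q_min: float = -5.0, q_max: float = 5.0, n_q: int = 100) -> np.ndarray:
    """Equidistant q grid, endpoints inclusive (default 100 values in [-5, 5])."""
    return np.linspace(q_min, q_max, n_q)


def default_scale_grid(
    s_min: int = 16, s_max: int = 256, n_scales: int = 16
) -> np.ndarray:
    """Integer scales log-spaced between ``s_min`` and ``s_max``, deduplicated."""
    raw = np.logspace(np.log2(s_min), np.log2(s_max), n_scales, base=2.0)
    return np.unique(np.round(raw).astype(int))


@dataclass(frozen=True)
class MfdfaConfig:
    """Parameters of an MF-DFA run.

    Defaults follow common practice for heart-rate series: 100 equidistant
    moment orders q in [-5, 5], 16 log-spaced scales from 16 to 256 samples,
    linear (order-1) detrending, forward-only binning.
    """

    q_grid: np.ndarray = field(default_factory=default_q_grid)
    scale_grid: np.ndarray = field(default_factory=default_scale_grid)
    detrend_order: int = 1
    bidirectional_bins: bool = False

    def __post_init__(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        s = np.asarray(self.scale_grid, dtype=int)
        if not np.all(np.isfinite(q)):
            raise HrvChaosError("q_grid must be finite")
        if np.any(s < self.detrend_order + 2):
            raise HrvChaosError(
                f"every scale must be >= detrend_order + 2 = {self.detrend_order + 2}"
            )
        object.__setattr__(self, "q_grid", q)
        object.__setattr__(self, "scale_grid", s)


@dataclass(frozen=True)
class MfdfaResult:
    """Full output of an MF-DFA run, intermediates included.

    ``fq_surface`` has shape (len(q_grid), len(scale_grid)).  ``hurst_q``,
    ``hurst_stderr`` and ``hurst_r2`` come from the per-q log-log regression;
    ``width = max(alpha) - min(alpha)`` over the finite q grid.
    """

    q_grid: np.ndarray
    scale_grid: np.ndarray
    fq_surface: np.ndarray
    hurst_q: np.ndarray
    hurst_stderr: np.ndarray
    hurst_r2: np.ndarray
    tau_q: np.ndarray
    alpha: np.ndarray
    f_alpha: np.ndarray
    width: float
    alpha_monotone: bool = True

    def h(self, q: float) -> float:
        """h at the grid point nearest to ``q``."""
        return float(self.hurst_q[np.argmin(np.abs(self.q_grid - q))])


def compute_profile(series: TimeSeries | np.ndarray) -> np.ndarray:
    """Integrated, mean-subtracted profile ``Y(i) = sum_{k<=i}(x(k) - mean)``.

    The last element telescopes to zero up to rounding.  A constant input
    yields the all-zero profile (valid here; degenerate bins are flagged
    downstream where they actually break the negative moments).
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    if x.size < 2:
        raise HrvChaosError("profile needs at least 2 samples")
    return np.cumsum(x - x.mean())


def _bin_squared_residuals(profile: np.ndarray, s: int, m: int, reverse: bool) -> np.ndarray:
    """Mean squared detrending residual for every bin of length s (vectorised)."""
    n_s = profile.size // s
    segment = profile[profile.size - n_s * s:] if reverse else profile[: n_s * s]
    bins = segment.reshape(n_s, s)
    # shared Vandermonde in the local coordinate i = 1..s; least squares once
    i = np.arange(1.0, s + 1.0)
    design = np.vander(i, m + 1)
    coef, *_ = np.linalg.lstsq(design, bins.T, rcond=None)
    resid = bins.T - design @ coef
    return np.mean(resid**2, axis=0)


def local_rms(profile: np.ndarray, s: int, v: int, m: int = 1) -> float:
    """Mean squared residual ``F2(s, v)`` of bin ``v`` (1-based) at scale ``s``.

    The bin covers profile samples ``(v-1)s + 1 .. v s``; the trend is the
    order-m least-squares polynomial over the bin.
    """
    profile = np.asarray(profile, dtype=float)
    if s < m + 2:
        raise HrvChaosError(f"scale s={s} too short for detrend order m={m}")
    n_s = profile.size // s
    if not 1 <= v <= n_s:
        raise HrvChaosError(f"bin index v={v} outside 1..{n_s}")
    return float(_bin_squared_residuals(profile, s, m, reverse=False)[v - 1])


def _fq_from_f2(f2: np.ndarray, q_grid: np.ndarray, s: int) -> np.ndarray:
    """q-th order generalized mean of the per-bin squared residuals."""
    out = np.empty(q_grid.size)
    zero_bins = f2 <= 0.0
    if np.any(zero_bins) and np.any(q_grid < -_Q_ZERO_TOL):
        raise DegenerateInputError(
            f"{int(zero_bins.sum())} bin(s) at scale {s} have zero detrending "
            "residual (constant segment): negative moments diverge. Reduce the "
            "detrend order or exclude this scale."
        )
    for j, q in enumerate(q_grid):
        if abs(q) < _Q_ZERO_TOL:
            out[j] = np.exp(0.5 * np.mean(np.log(f2)))
        else:
            out[j] = np.mean(f2 ** (q / 2.0)) ** (1.0 / q)
    return out


def fluctuation_function(
    series: TimeSeries | np.ndarray, config: MfdfaConfig | None = None
) -> np.ndarray:
    """Fluctuation surface ``F_q(s)``, rows indexed by q, columns by scale.

    For each q the entry is the generalized (power q) mean over bins of the
    RMS detrending residual; by the generalized-mean inequality the surface is
    non-decreasing in q at every scale.
    """
    config = config or MfdfaConfig()
    profile = compute_profile(series)
    n = profile.size
    if n < 4 * int(np.max(config.scale_grid)):
        raise HrvChaosError(
            f"series of length {n} too short for max scale "
            f"{int(np.max(config.scale_grid))} (need N >= 4*s_max)"
        )
    surface = np.empty((config.q_grid.size, config.scale_grid.size))
    for col, s in enumerate(config.scale_grid):
        f2 = _bin_squared_residuals(profile, int(s), config.detrend_order, reverse=False)
        if config.bidirectional_bins:
            f2 = np.concatenate(
                [f2, _bin_squared_residuals(profile, int(s), config.detrend_order, reverse=True)]
            )
        surface[:, col] = _fq_from_f2(f2, config.q_grid, int(s))
    return surface


def generalized_hurst(
    fq_surface: np.ndarray, scale_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-q OLS slope of ``log2 F_q(s)`` on ``log2 s``: (h(q), stderr, R^2).

    Non-finite surface entries are excluded per q; fewer than 4 usable scales
    is an error.
    """
    fq_surface = np.atleast_2d(np.asarray(fq_surface, dtype=float))
    log_s = np.log2(np.asarray(scale_grid, dtype=float))
    n_q = fq_surface.shape[0]
    h = np.empty(n_q)
    stderr = np.empty(n_q)
    r2 = np.empty(n_q)
    for j in range(n_q):
        with np.errstate(divide="ignore", invalid="ignore"):
            log_f = np.log2(fq_surface[j])
        ok = np.isfinite(log_f)
        if ok.sum() < 4:
            raise HrvChaosError(
                f"fewer than 4 finite scales for q index {j}; cannot fit h(q)"
            )
        fit = stats.linregress(log_s[ok], log_f[ok])
        h[j] = fit.slope
        stderr[j] = fit.stderr
        r2[j] = fit.rvalue**2
    return h, stderr, r2


def tau_from_h(h_q: np.ndarray, q_grid: np.ndarray) -> np.ndarray:
    """Mass scaling exponent ``tau(q) = q h(q) - 1`` (linear in q iff monofractal)."""
    return np.asarray(q_grid, float) * np.asarray(h_q, float) - 1.0


def singularity_spectrum(
    h_q: np.ndarray, q_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Legendre-transform pair ``alpha = h + q h'``, ``f = q (alpha - h) + 1``.

    h'(q) is computed by central finite differences on the q grid (one-sided
    at the endpoints).  Noisy h(q) can make alpha non-monotone; the spectrum
    is still returned (the width remains max - min) and callers can inspect
    monotonicity via the result diagnostics.
    """
    h_q = np.asarray(h_q, dtype=float)
    q_grid = np.asarray(q_grid, dtype=float)
    if h_q.size < 3:
        raise HrvChaosError("singularity spectrum needs h(q) on >= 3 grid points")
    dh = np.gradient(h_q, q_grid)
    alpha = h_q + q_grid * dh
    f_alpha = q_grid * (alpha - h_q) + 1.0
    return alpha, f_alpha


def spectrum_width(alpha: np.ndarray) -> float:
    """Multifractal spectrum width ``max(alpha) - min(alpha)`` (>= 0)."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.size == 0:
        raise HrvChaosError("alpha is empty")
    return float(alpha.max() - alpha.min())


def run_mfdfa(series: TimeSeries | np.ndarray, config: MfdfaConfig | None = None) -> MfdfaResult:
    """Run the full MF-DFA chain and return all intermediates.

    Deterministic.  Emits a warning for series shorter than
    ``RELIABLE_MIN_LENGTH`` samples: with few bins per scale the h(q)
    regression — and hence the width — becomes unreliable.
    """
    config = config or MfdfaConfig()
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    if x.size < RELIABLE_MIN_LENGTH:
        warnings.warn(
            f"MF-DFA unreliable below N~{RELIABLE_MIN_LENGTH} samples (got {x.size})",
            stacklevel=2,
        )
    surface = fluctuation_function(series, config)
    h, stderr, r2 = generalized_hurst(surface, config.scale_grid)
    tau = tau_from_h(h, config.q_grid)
    alpha, f_alpha = singularity_spectrum(h, config.q_grid)
    # alpha should decrease with q for a clean multifractal; flag if noisy
    monotone = bool(np.all(np.diff(alpha) <= 1e-12) or np.all(np.diff(alpha) >= -1e-12))
    return MfdfaResult(
        q_grid=config.q_grid,
        scale_grid=config.scale_grid,
        fq_surface=surface,
        hurst_q=h,
        hurst_stderr=stderr,
        hurst_r2=r2,
        tau_q=tau,
        alpha=alpha,
        f_alpha=f_alpha,
        width=spectrum_width(alpha),
        alpha_monotone=monotone,
    )
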