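"""Shared fixtures: synthetic subjects and the brute-force visibility oracle."""

from __future__ import annotations

import numpy as np
import pytest

import hrvchaos as hc
from hrvchaos.core import TimeSeries

N_SUBJECT = 8192


def make_pre_series(seed: int, n: int = N_SUBJECT) -> TimeSeries:
    """Rest-state stand-in: smooth oscillation, small monofractal variability."""
    return hc.generate_bpm_like(
        baseline=72.0, osc_amplitude=8.0, osc_period=300.0,
        hurst=0.6, noise_scale=2.0, n=n, seed=seed,
    )


def make_med_series(seed: int, n: int = N_SUBJECT) -> TimeSeries:
    """Meditation-state stand-in: larger, cascade-modulated (multifractal)
    beat-to-beat variability on the same baseline."""
    env = hc.generate_binomial_cascade(0.65, 13).values[:n] ** 0.5
    env = env / env.mean()
    noise = hc.generate_fgn(0.6, n, seed).values * env
    noise = 6.0 * noise / noise.std()
    osc = 5.0 * np.sin(2.0 * np.pi * np.arange(n) / 300.0)
    return TimeSeries(72.0 + osc + noise, label=f"synthetic meditation (seed={seed})")


def brute_force_visibility_edges(x: np.ndarray) -> set[tuple[int, int]]:
    """O(n^3) literal evaluation of the visibility criterion (test oracle)."""
    n = len(x)
    edges = set()
    for m in range(n):
        for nn in range(m + 1, n):
            if all(
                x[t] < x[nn] + (nn - t) / (nn - m) * (x[m] - x[nn])
                for t in range(m + 1, nn)
            ):
                edges.add((m, nn))
    return edges


@pytest.fixture(scope="session")
def cascade_a06() -> TimeSeries:
    return hc.generate_binomial_cascade(0.6, 13)


@pytest.fixture(scope="session")
def dyadic_scales() -> np.ndarray:
    """Scales commensurate with the cascade's dyadic construction."""
    return 2 ** np.arange(4, 9)
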