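"""Shared containers and errors for heart-rate time-series analysis.

The analyses in this package treat an instantaneous heart-rate recording
(beats/minute sampled once per detected beat) as an ordered sequence of real
samples.  Time stamps, when present, are carried as metadata only: both the
multifractal and the visibility-graph methods operate on sample order, not on
wall-clock spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "HrvChaosError", "DegenerateInputError"]


class HrvChaosError(ValueError):
    """Base class for errors raised by this package."""


class DegenerateInputError(HrvChaosError):
    """Input is structurally valid but degenerate for the requested analysis."""


@dataclass(frozen=True)
class TimeSeries:
    """An ordered real-valued sample sequence, optionally time-stamped.

    Parameters
    ----------
    values
        Sample values (BPM for heart-rate data, arbitrary units for synthetic
        series).  Must be finite and contain at least two samples.
    times
        Optional sample times in seconds, strictly increasing, same length as
        ``values``.  Carried as metadata; no analysis resamples on it.
    label
        Free-text identifier, e.g. ``"C1 meditation"``.
    """

    values: np.ndarray
    times: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise HrvChaosError(
                f"a time series needs at least 2 samples in one dimension, "
                f"got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise HrvChaosError("time-series values must be finite")
        object.__setattr__(self, "values", values)
        if self.times is not None:
            times = np.asarray(self.times, dtype=float)
            if times.shape != values.shape:
                raise HrvChaosError(
                    f"times length {times.size} != values length {values.size}"
                )
            if not np.all(np.diff(times) > 0):
                raise HrvChaosError("times must be strictly increasing")
            object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return int(self.values.size)
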