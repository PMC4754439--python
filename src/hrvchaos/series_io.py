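"""Reading and writing the plain-text BPM dialect and analysis outputs.

Input files are whitespace-delimited text with either two columns (elapsed
time in seconds, instantaneous heart rate in BPM) or a single BPM column —
the dialect used by the PhysioNet meditation database exports.  Lines
starting with ``#`` are comments.

Note that instantaneous heart rate is sampled once per beat and therefore
unevenly in time.  Both analyses in this package deliberately ignore the
time stamps and operate on sample order; times are carried as metadata only.
"""

from __future__ import annotations

import dataclasses
import json
from enum import Enum
from pathlib import Path
from typing import Any

import numpy as np

from .core import HrvChaosError, TimeSeries

__all__ = [
    "MeditationState",
    "SubjectRecord",
    "read_bpm_series",
    "write_series",
    "write_result",
    "result_to_dict",
]

SCHEMA_VERSION = 1


class MeditationState(str, Enum):
    PRE_MEDITATION = "pre_meditation"
    MEDITATION = "meditation"


@dataclasses.dataclass(frozen=True)
class SubjectRecord:
    """One subject/state recording (e.g. C3 during meditation)."""

    subject_id: str
    state: MeditationState
    series: TimeSeries

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise HrvChaosError("subject_id must be nonempty")


def read_bpm_series(
    path: str | Path, label: str = "", require_positive: bool = True
) -> TimeSeries:
    """Read a BPM series from two-column (time, BPM) or one-column text.

    Rejects non-numeric rows (with line number), non-finite values,
    non-increasing time stamps and — by default — non-positive values, since
    a heart rate of 0 BPM is a recording artefact.  Synthetic series written
    by this package's generators may legitimately be negative; pass
    ``require_positive=False`` for those.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    n_cols: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if n_cols is None:
                if len(fields) not in (1, 2):
                    raise HrvChaosError(
                        f"{path}:{lineno}: expected 1 or 2 columns, got {len(fields)}"
                    )
                n_cols = len(fields)
            elif len(fields) != n_cols:
                raise HrvChaosError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(fields)} vs {n_cols})"
                )
            try:
                row = [float(f) for f in fields]
            except ValueError as exc:
                raise HrvChaosError(f"{path}:{lineno}: non-numeric value: {exc}") from exc
            if not all(np.isfinite(row)):
                raise HrvChaosError(f"{path}:{lineno}: non-finite value")
            if n_cols == 2:
                times.append(row[0])
                values.append(row[1])
            else:
                values.append(row[0])
    if not values:
        raise HrvChaosError(f"{path}: no data rows")
    vals = np.asarray(values)
    if require_positive and np.any(vals <= 0):
        bad = int(np.argmax(vals <= 0))
        raise HrvChaosError(
            f"{path}: non-positive BPM value {vals[bad]} at data row {bad + 1} "
            "(pass require_positive=False for non-BPM series)"
        )
    t = np.asarray(times) if times else None
    if t is not None and not np.all(np.diff(t) > 0):
        raise HrvChaosError(f"{path}: time stamps are not strictly increasing")
    return TimeSeries(values=vals, times=t, label=label or path.stem)


def write_series(series: TimeSeries, path: str | Path) -> None:
    """Write a series as two-column text (time-or-index, value)."""
    path = Path(path)
    t = series.times if series.times is not None else np.arange(len(series), dtype=float)
    with path.open("w") as fh:
        if series.label:
            fh.write(f"# {series.label}\n")
        for ti, vi in zip(t, series.values):
            fh.write(f"{ti:.6f} {vi:.10g}\n")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, Enum):
        return obj.value
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def result_to_dict(result: Any) -> dict:
    """Schema-versioned plain-dict form of any result dataclass."""
    return {
        "schema_version": SCHEMA_VERSION,
        "type": type(result).__name__,
        **_jsonable(result),
    }


def write_result(result: Any, path: str | Path, format: str = "json") -> None:
    """Write an analysis result (MF-DFA, PSVG fit or comparison table).

    JSON serialises the full dataclass, schema-versioned.  CSV writes the
    natural tabular view: the F_q(s) surface for an MF-DFA result, the
    (k, P(k)) table for a PSVG fit, and the subject-by-subject summary table
    (columns subject, lambda_med, lambda_pre, width_med, width_pre,
    shuffled_width_med, shuffled_width_pre) for a comparison table.
    """
    from .pipeline import ComparisonTable  # local import to avoid a cycle

    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(result_to_dict(result), indent=2) + "\n")
        return
    if format != "csv":
        raise HrvChaosError(f"unknown format {format!r}; use 'json' or 'csv'")

    import pandas as pd

    from .mfdfa import MfdfaResult
    from .visibility import PsvgFit

    if isinstance(result, MfdfaResult):
        frame = pd.DataFrame(
            result.fq_surface,
            index=pd.Index(result.q_grid, name="q"),
            columns=[f"s={s}" for s in result.scale_grid],
        )
        frame.to_csv(path)
    elif isinstance(result, PsvgFit):
        pd.DataFrame({"k": result.k_values, "p_k": result.p_k}).to_csv(path, index=False)
    elif isinstance(result, ComparisonTable):
        result.to_frame().to_csv(path, index=False, float_format="%.6g")
    else:
        raise HrvChaosError(f"no CSV writer for {type(result).__name__}")
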