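"""Pre- vs during-meditation comparison across both analysis methods.

For every subject the pipeline computes the PSVG exponent (lambda) and the
MF-DFA spectrum width in both states, the spectrum width of shuffled
surrogates as a correlation-free baseline, and the percent increase of each
quantity from the pre-meditation to the meditation state.  Across subjects it
summarises the per-group range of increases, state means, and the Pearson
correlation between the two methods' values — pooled over both states,
within the meditation state, and within the pre-meditation state.

MF-DFA needs long series; for short recordings (the Kundalini Yoga group in
the reference dataset) the width columns are suppressed and only the
visibility-graph exponent is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import HrvChaosError, TimeSeries
from .mfdfa import RELIABLE_MIN_LENGTH, MfdfaConfig, run_mfdfa
from .synthetic import shuffle_series
from .visibility import psvg_of_series

__all__ = [
    "SubjectComparison",
    "ComparisonTable",
    "percent_increase",
    "pearson",
    "analyze_subject",
    "build_table",
    "plot_comparison",
]


def percent_increase(pre_value: float, med_value: float) -> float:
    """Percent change from the pre-meditation to the meditation value.

    ``100 * (med - pre) / pre``; sign-preserving, zero when equal.
    """
    if pre_value <= 0:
        raise HrvChaosError(f"pre-meditation value must be positive, got {pre_value}")
    return 100.0 * (med_value - pre_value) / pre_value


def pearson(xs, ys) -> float:
    """Sample Pearson correlation coefficient of two equal-length sequences."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size or xs.size < 3:
        raise HrvChaosError("pearson needs two equal-length sequences of length >= 3")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise HrvChaosError("pearson undefined for zero-variance input")
    return float(stats.pearsonr(xs, ys).statistic)


@dataclass(frozen=True)
class SubjectComparison:
    """Per-subject pre/meditation values for both methods.

    Width fields are ``None`` when MF-DFA was suppressed (series too short
    for a reliable multifractal width).
    """

    subject_id: str
    lambda_pre: float
    lambda_med: float
    width_pre: float | None = None
    width_med: float | None = None
    shuffled_width_pre: float | None = None
    shuffled_width_med: float | None = None
    group: str = ""

    @property
    def pct_increase_lambda(self) -> float:
        return percent_increase(self.lambda_pre, self.lambda_med)

    @property
    def pct_increase_width(self) -> float | None:
        if self.width_pre is None or self.width_med is None:
            return None
        return percent_increase(self.width_pre, self.width_med)

    @property
    def has_mfdfa(self) -> bool:
        return self.width_pre is not None and self.width_med is not None


@dataclass(frozen=True)
class ComparisonTable:
    """Subject-by-subject comparison with group summaries and correlations.

    ``r_all`` pools the (lambda, width) pairs of both states over subjects
    with MF-DFA present; ``r_med`` / ``r_pre`` restrict to one state.  Group
    summaries hold min/max percent increases and state means of lambda.
    Correlations are ``nan`` when fewer than 3 subjects carry widths.
    """

    rows: tuple[SubjectComparison, ...]
    r_all: float = math.nan
    r_med: float = math.nan
    r_pre: float = math.nan
    group_summaries: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject": r.subject_id,
                    "lambda_med": r.lambda_med,
                    "lambda_pre": r.lambda_pre,
                    "width_med": r.width_med,
                    "width_pre": r.width_pre,
                    "shuffled_width_med": r.shuffled_width_med,
                    "shuffled_width_pre": r.shuffled_width_pre,
                }
                for r in self.rows
            ],
            columns=[
                "subject",
                "lambda_med",
                "lambda_pre",
                "width_med",
                "width_pre",
                "shuffled_width_med",
                "shuffled_width_pre",
            ],
        )


def analyze_subject(
    subject_id: str,
    pre_series: TimeSeries,
    med_series: TimeSeries,
    mfdfa_config: MfdfaConfig | None = None,
    shuffle_seed: int = 0,
    suppress_mfdfa: bool | None = None,
    n_shuffles: int = 1,
    group: str = "",
    psvg_k_min: int | None = None,
    psvg_k_max: int | None = None,
) -> SubjectComparison:
    """Run both methods on one subject's pre- and meditation recordings.

    ``suppress_mfdfa=None`` suppresses automatically when either series is
    shorter than the MF-DFA reliability floor (1024 samples).  Shuffled
    baseline widths are averaged over ``n_shuffles`` seeded surrogates
    (default one, i.e. a single permutation per state).  ``psvg_k_min`` /
    ``psvg_k_max`` restrict the PSVG fit to a degree window (default: all
    observed degrees).
    """
    lam_pre = psvg_of_series(pre_series, k_min=psvg_k_min, k_max=psvg_k_max).lambda_p
    lam_med = psvg_of_series(med_series, k_min=psvg_k_min, k_max=psvg_k_max).lambda_p
    if suppress_mfdfa is None:
        suppress_mfdfa = min(len(pre_series), len(med_series)) < RELIABLE_MIN_LENGTH
    if suppress_mfdfa:
        return SubjectComparison(
            subject_id=subject_id, lambda_pre=lam_pre, lambda_med=lam_med, group=group
        )
    config = mfdfa_config or MfdfaConfig()

    def shuffled_width(series: TimeSeries, base_seed: int) -> float:
        widths = [
            run_mfdfa(shuffle_series(series, base_seed + r), config).width
            for r in range(n_shuffles)
        ]
        return float(np.mean(widths))

    return SubjectComparison(
        subject_id=subject_id,
        lambda_pre=lam_pre,
        lambda_med=lam_med,
        width_pre=run_mfdfa(pre_series, config).width,
        width_med=run_mfdfa(med_series, config).width,
        shuffled_width_pre=shuffled_width(pre_series, shuffle_seed),
        shuffled_width_med=shuffled_width(med_series, shuffle_seed + 10_000),
        group=group,
    )


def _summarise_group(rows: list[SubjectComparison]) -> dict:
    lam_pct = [r.pct_increase_lambda for r in rows]
    width_pct = [r.pct_increase_width for r in rows if r.pct_increase_width is not None]
    out = {
        "n_subjects": len(rows),
        "lambda_pct_min": min(lam_pct),
        "lambda_pct_max": max(lam_pct),
        "mean_lambda_med": float(np.mean([r.lambda_med for r in rows])),
        "mean_lambda_pre": float(np.mean([r.lambda_pre for r in rows])),
    }
    if width_pct:
        out["width_pct_min"] = min(width_pct)
        out["width_pct_max"] = max(width_pct)
    return out


def build_table(comparisons) -> ComparisonTable:
    """Aggregate per-subject comparisons into the summary table.

    Cross-method correlations use the subjects with MF-DFA present, pairing
    each state's lambda with the same state's width; the pooled value stacks
    both states.
    """
    rows = tuple(comparisons)
    if not rows:
        raise HrvChaosError("build_table needs at least one comparison")
    with_width = [r for r in rows if r.has_mfdfa]
    r_all = r_med = r_pre = math.nan
    if len(with_width) >= 3:
        lam_med = [r.lambda_med for r in with_width]
        lam_pre = [r.lambda_pre for r in with_width]
        w_med = [r.width_med for r in with_width]
        w_pre = [r.width_pre for r in with_width]

        def safe_pearson(xs, ys):
            try:
                return pearson(xs, ys)
            except HrvChaosError:  # zero variance: correlation undefined
                return math.nan

        r_med = safe_pearson(lam_med, w_med)
        r_pre = safe_pearson(lam_pre, w_pre)
        r_all = safe_pearson(lam_med + lam_pre, w_med + w_pre)
    groups: dict[str, list[SubjectComparison]] = {}
    for r in rows:
        groups.setdefault(r.group, []).append(r)
    summaries = {g: _summarise_group(members) for g, members in groups.items()}
    return ComparisonTable(
        rows=rows, r_all=r_all, r_med=r_med, r_pre=r_pre, group_summaries=summaries
    )


def plot_comparison(table: ComparisonTable, path) -> None:
    """Best-effort summary figure: per-subject lambda (and width) by state.

    Dotted lines mark per-group state means.  Cosmetic output only; nothing
    downstream depends on it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    has_width = any(r.has_mfdfa for r in table.rows)
    fig, axes = plt.subplots(1, 2 if has_width else 1, figsize=(10, 4), squeeze=False)
    ax = axes[0][0]
    ids = [r.subject_id for r in table.rows]
    ax.plot(ids, [r.lambda_med for r in table.rows], "o-", label="meditation")
    ax.plot(ids, [r.lambda_pre for r in table.rows], "s-", label="pre-meditation")
    for g, s in table.group_summaries.items():
        ax.axhline(s["mean_lambda_med"], ls=":", color="C0", alpha=0.6)
        ax.axhline(s["mean_lambda_pre"], ls=":", color="C1", alpha=0.6)
    ax.set_ylabel(r"PSVG exponent $\lambda_p$")
    ax.legend()
    if has_width:
        ax2 = axes[0][1]
        ww = [r for r in table.rows if r.has_mfdfa]
        ids2 = [r.subject_id for r in ww]
        ax2.plot(ids2, [r.width_med for r in ww], "o-", label="meditation")
        ax2.plot(ids2, [r.width_pre for r in ww], "s-", label="pre-meditation")
        ax2.set_ylabel(r"MF-DFA spectrum width $\Delta\alpha$")
        ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
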