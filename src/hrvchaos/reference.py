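"""Published per-subject reference values for the PhysioNet meditation cohort.

PSVG exponents (lambda) and MF-DFA spectrum widths reported for the eight Chi
meditation subjects (C1-C8) and four Kundalini Yoga subjects (Y1-Y4) of the
PhysioNet meditation heart-rate database, in the pre-meditation and
meditation states, together with the shuffled-surrogate baseline widths for
the Chi group.  MF-DFA values for the Kundalini group were not reported
(recordings too short for a reliable width) and are absent here.

These numbers are published summary statistics, not raw data: they let the
comparison arithmetic (percent increases, cross-method correlations) be
recomputed and checked without downloading the recordings.
"""

from __future__ import annotations

from .pipeline import ComparisonTable, SubjectComparison, build_table

__all__ = ["REFERENCE_SUBJECTS", "reference_table"]

CHI = "Chi"
KUNDALINI = "Kundalini"

#: (subject, group, lambda_med, lambda_pre, width_med, width_pre,
#:  shuffled_width_med, shuffled_width_pre); widths None where unreported
REFERENCE_SUBJECTS: tuple[tuple, ...] = (
    ("C1", CHI, 5.49, 3.22, 0.66, 0.24, 0.13, 0.19),
    ("C2", CHI, 3.83, 2.95, 0.43, 0.21, 0.08, 0.09),
    ("C3", CHI, 3.90, 2.94, 0.59, 0.30, 0.21, 0.05),
    ("C4", CHI, 3.96, 2.61, 0.45, 0.39, 0.05, 0.02),
    ("C5", CHI, 3.49, 3.01, 0.41, 0.31, 0.26, 0.17),
    ("C6", CHI, 3.89, 3.12, 0.28, 0.28, 0.14, 0.14),
    ("C7", CHI, 3.07, 2.33, 0.53, 0.32, 0.16, 0.22),
    ("C8", CHI, 3.89, 3.45, 0.68, 0.43, 0.09, 0.11),
    ("Y1", KUNDALINI, 5.19, 1.42, None, None, None, None),
    ("Y2", KUNDALINI, 3.25, 1.90, None, None, None, None),
    ("Y3", KUNDALINI, 3.60, 2.28, None, None, None, None),
    ("Y4", KUNDALINI, 1.94, 1.32, None, None, None, None),
)


def reference_table() -> ComparisonTable:
    """The published cohort as a :class:`ComparisonTable`.

    Correlations and group summaries are recomputed from the subject values,
    not copied from any published summary.
    """
    rows = [
        SubjectComparison(
            subject_id=sid,
            lambda_med=lam_med,
            lambda_pre=lam_pre,
            width_med=w_med,
            width_pre=w_pre,
            shuffled_width_med=sw_med,
            shuffled_width_pre=sw_pre,
            group=group,
        )
        for sid, group, lam_med, lam_pre, w_med, w_pre, sw_med, sw_pre in REFERENCE_SUBJECTS
    ]
    return build_table(rows)
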