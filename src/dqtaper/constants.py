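"""Shared constants: the follow-up grid, analysis intervals, thresholds, bounds.

The follow-up schedule is every 3 months in the first year and every
6 months in the second, giving the canonical visit grid below.  Follow-up
is partitioned into five analysis intervals; the 12-24 month interval
spans two visit gaps and gets the (1,2,1)/4 endpoint weighting when the
average dose quotient is formed.
"""

from __future__ import annotations

#: Canonical visit months.  Other months are rejected, not binned.
CANONICAL_MONTHS: tuple[int, ...] = (0, 3, 6, 9, 12, 18, 24)

#: Analysis intervals: label -> (t_start, t_end) in months.
INTERVALS: dict[str, tuple[int, int]] = {
    "I1": (0, 3),
    "I2": (3, 6),
    "I3": (6, 9),
    "I4": (9, 12),
    "I5": (12, 24),
}

#: Interval labels in chronological order.
INTERVAL_ORDER: tuple[str, ...] = ("I1", "I2", "I3", "I4", "I5")

#: ASDAS-CRP below this is inactive disease (remission).
REMISSION_THRESHOLD: float = 1.3

#: ASDAS-CRP below this is low disease activity; at or above it, high.
#: Interval status classification keys on this threshold.
LOW_DISEASE_THRESHOLD: float = 2.1

#: Default instrument score bounds used for validation and simulation
#: clipping: SPARCC 0-72; SSS components fat 0-40, erosion 0-40,
#: backfill 0-20.
SCORE_BOUNDS: dict[str, tuple[float, float]] = {
    "sparcc": (0.0, 72.0),
    "fat": (0.0, 40.0),
    "erosion": (0.0, 40.0),
    "backfill": (0.0, 20.0),
}

#: MRI score columns, in canonical order.
MRI_SCORES: tuple[str, ...] = ("sparcc", "fat", "erosion", "backfill")

#: Reference-coded baseline covariates used by the treatment models.
#: Reference levels: female, nr-axSpA, HLA-B27 negative, non-smoker.
BASELINE_COVARIATES: tuple[str, ...] = (
    "sex_male",
    "age",
    "diagnosis_as",
    "duration",
    "smoking",
    "hla_b27",
)
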