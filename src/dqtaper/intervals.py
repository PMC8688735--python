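"""Partition follow-up into analysis intervals and build the intervals table.

Each patient's two years of follow-up is split into five intervals
(0-3, 3-6, 6-9, 9-12, 12-24 months), so a 108-patient cohort yields 540
interval records.  Each record carries the interval-average dose
quotient, the ASDAS-CRP endpoints and the response/relapse status,
the per-interval changes in the four MRI scores (end minus start, after
linear interpolation of any interior gaps), the bone-marrow-edema
status (SPARCC increased or not), and an IPTW weight (1 until weights
are computed).

Status classification evaluates the four clinical rules at interval
endpoints (the visit grid provides no finer resolution): an interval is
a *response* when ASDAS-CRP at its end is below 2.1 — this covers both
"remained in remission/low disease activity" and "fell from high to
low" — and a *relapse* otherwise (rose to, or stayed at, high disease
activity).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort, baseline_table
from .constants import (
    BASELINE_COVARIATES,
    CANONICAL_MONTHS,
    INTERVALS,
    INTERVAL_ORDER,
    LOW_DISEASE_THRESHOLD,
    MRI_SCORES,
)
from .dosing import DqTimeline, Regimen, average_dq, timelines_from_doses
from .errors import ClassificationError, ImputationError
from . import dosing

__all__ = [
    "partition",
    "classify_status",
    "interpolate_series",
    "complete_mri",
    "interval_deltas",
    "attach_exposure",
    "build_interval_table",
]

#: Columns of the intervals table, the exchange format between stages.
INTERVAL_COLUMNS = (
    "patient_id",
    "interval_id",
    "t_start",
    "t_end",
    "avg_dq",
    "asdas_start",
    "asdas_end",
    "status",
    "d_sparcc",
    "d_fat",
    "d_erosion",
    "d_backfill",
    "sparcc_increased",
    "weight",
)


def partition(patient_ids) -> pd.DataFrame:
    """Interval skeleton: one row per (patient, interval), 5 per patient."""
    pids = [str(p) for p in patient_ids]
    rows = [
        {
            "patient_id": pid,
            "interval_id": iid,
            "t_start": INTERVALS[iid][0],
            "t_end": INTERVALS[iid][1],
        }
        for pid in pids
        for iid in INTERVAL_ORDER
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "interval_id", "t_start", "t_end"]
    )


def classify_status(asdas_start: float, asdas_end: float) -> str:
    """Response/relapse status of one interval from its ASDAS-CRP endpoints.

    Evaluated at endpoints, the four clinical rules reduce to the state
    at the interval end: *response* iff ASDAS-CRP end < 2.1 (remained
    low, or fell from high to low); *relapse* otherwise (rose to high,
    or remained high).
    """
    if asdas_start is None or asdas_end is None:
        raise ClassificationError("missing ASDAS-CRP endpoint")
    if np.isnan(asdas_start) or np.isnan(asdas_end):
        raise ClassificationError("missing (NaN) ASDAS-CRP endpoint")
    if asdas_start < 0 or asdas_end < 0:
        raise ClassificationError("ASDAS-CRP endpoints must be non-negative")
    return "response" if asdas_end < LOW_DISEASE_THRESHOLD else "relapse"


def interpolate_series(
    points: Mapping[int, float],
    grid=CANONICAL_MONTHS,
) -> tuple[dict[int, float], dict[int, bool]]:
    """Complete a sparse (month -> value) series on ``grid`` by linear
    interpolation between the nearest measured neighbours.

    Returns (values, measured flags).  Measured points are returned
    unchanged; leading or trailing gaps are an error (no extrapolation).
    """
    grid = sorted(grid)
    measured_months = sorted(points)
    if not measured_months:
        raise ImputationError("no measured points to interpolate from")
    if grid[0] not in points or grid[-1] not in points:
        missing = [m for m in (grid[0], grid[-1]) if m not in points]
        raise ImputationError(
            f"cannot extrapolate: boundary months {missing} unmeasured"
        )
    xm = np.array(measured_months, dtype=float)
    ym = np.array([points[m] for m in measured_months], dtype=float)
    values: dict[int, float] = {}
    flags: dict[int, bool] = {}
    for m in grid:
        if m in points:
            values[m] = float(points[m])
            flags[m] = True
        else:
            values[m] = float(np.interp(m, xm, ym))
            flags[m] = False
    return values, flags


def complete_mri(cohort: Cohort) -> pd.DataFrame:
    """MRI table completed on the full grid, imputed rows flagged measured=0."""
    out_rows = []
    for pid, grp in cohort.mri.groupby("patient_id", sort=True):
        grp = grp.loc[grp["measured"] == 1]
        series = {}
        flags = None
        for score in MRI_SCORES:
            pts = {
                int(r.month): float(getattr(r, score))
                for r in grp.itertuples(index=False)
            }
            series[score], flags = interpolate_series(pts)
        for m in CANONICAL_MONTHS:
            out_rows.append(
                {
                    "patient_id": str(pid),
                    "month": m,
                    **{score: series[score][m] for score in MRI_SCORES},
                    "measured": int(flags[m]),
                }
            )
    return pd.DataFrame(
        out_rows, columns=["patient_id", "month", *MRI_SCORES, "measured"]
    )


def interval_deltas(
    mri_complete: pd.DataFrame,
    skeleton: pd.DataFrame,
) -> pd.DataFrame:
    """Fill d_sparcc/d_fat/d_erosion/d_backfill and sparcc_increased.

    d_x = x(t_end) - x(t_start); SPARCC counts as increased only for a
    strictly positive change.
    """
    idx = mri_complete.set_index(["patient_id", "month"])
    out = skeleton.copy()
    start_keys = list(zip(out["patient_id"], out["t_start"]))
    end_keys = list(zip(out["patient_id"], out["t_end"]))
    for score in MRI_SCORES:
        series = idx[score]
        out[f"d_{score}"] = (
            series.loc[end_keys].to_numpy() - series.loc[start_keys].to_numpy()
        )
    out["sparcc_increased"] = out["d_sparcc"] > 0
    return out


def attach_exposure(
    skeleton: pd.DataFrame,
    timelines: Mapping[str, DqTimeline],
    visits: pd.DataFrame,
) -> pd.DataFrame:
    """Populate avg_dq, ASDAS-CRP endpoints and response/relapse status."""
    asdas = visits.set_index(["patient_id", "month"])["asdas_crp"]
    out = skeleton.copy()
    avg, a0, a1, status = [], [], [], []
    for row in out.itertuples(index=False):
        pid = str(row.patient_id)
        tl = timelines[pid]
        avg.append(average_dq(tl, row.interval_id))
        s = float(asdas.loc[(pid, row.t_start)])
        e = float(asdas.loc[(pid, row.t_end)])
        a0.append(s)
        a1.append(e)
        status.append(classify_status(s, e))
    out["avg_dq"] = avg
    out["asdas_start"] = a0
    out["asdas_end"] = a1
    out["status"] = status
    return out


def build_interval_table(
    cohort: Cohort,
    registry: Mapping[str, Regimen] | None = None,
) -> pd.DataFrame:
    """The full intervals table for a cohort, weight initialised to 1.

    Baseline covariates (reference-coded) and the treatment group are
    merged in so the table is self-sufficient for weighting, GEE, ROC
    and survival stages.
    """
    if registry is None:
        registry = dosing.default_registry()
    skeleton = partition(cohort.patients["patient_id"])
    timelines = timelines_from_doses(cohort.doses, registry)
    table = attach_exposure(skeleton, timelines, cohort.visits)
    table = interval_deltas(complete_mri(cohort), table)
    table["weight"] = 1.0
    base = baseline_table(cohort)[
        ["patient_id", "group", *BASELINE_COVARIATES]
    ]
    table = table.merge(base, on="patient_id", how="left")
    order = [c for c in INTERVAL_COLUMNS if c in table.columns] + [
        "group",
        *BASELINE_COVARIATES,
    ]
    return table[order]
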