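"""Dose-quotient (DQ) scoring of TNFi regimens.

The dose quotient expresses any actual regimen as a percentage of the
drug's standard regimen::

    DQ = (actual dose / standard dose)
         x (standard dosing interval / actual dosing interval) x 100

so the full standard regimen scores 100, etanercept 25 mg weekly against
a standard of 25 mg twice weekly scores 50, and withdrawal scores 0.
DQ is invariant to scaling dose and interval together (50 mg every 7
days equals 25 mg every 3.5 days) and is deliberately not capped at 100
so dose escalation stays representable.

Tapering proceeds in three-month phases along one of two tracks:
two-thirds (100 -> 66.7 -> 35 -> 16.7) or half (100 -> 50 -> 25 ->
12.5) of the full dose.

The interval-average DQ is the mean of the two endpoint DQs for the
3-month intervals and ``(DQ12 + 2*DQ18 + DQ24) / 4`` for the 12-24
month interval (the mean of the two half-interval means).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .constants import CANONICAL_MONTHS, INTERVALS
from .errors import (
    DqTaperError,
    IncompleteTimelineError,
    UnknownRegimenError,
)

__all__ = [
    "Regimen",
    "DqTimeline",
    "load_registry",
    "default_registry",
    "compute_dq",
    "build_timeline",
    "timelines_from_doses",
    "average_dq",
    "taper_schedule",
    "TAPER_TRACKS",
]

#: Planned post-reduction DQ levels per taper track (phase 1, 2, 3).
TAPER_TRACKS: dict[str, tuple[float, float, float]] = {
    "two-thirds": (66.7, 35.0, 16.7),
    "half": (50.0, 25.0, 12.5),
}


@dataclass(frozen=True)
class Regimen:
    """Standard (full-dose) regimen of one TNFi drug.

    ``standard_dose`` is in mg (mg per kg for weight-based drugs such as
    infliximab); ``standard_interval`` is in days.
    """

    drug: str
    standard_dose: float
    standard_interval: float

    def __post_init__(self) -> None:
        if not self.standard_dose > 0:
            raise DqTaperError(
                f"regimen {self.drug!r}: standard_dose must be > 0"
            )
        if not self.standard_interval > 0:
            raise DqTaperError(
                f"regimen {self.drug!r}: standard_interval must be > 0"
            )


@dataclass(frozen=True)
class DqTimeline:
    """Per-patient DQ series defined at every canonical month."""

    patient_id: str
    dq: Mapping[int, float] = field(hash=False)

    def __post_init__(self) -> None:
        missing = [m for m in CANONICAL_MONTHS if m not in self.dq]
        if missing:
            raise IncompleteTimelineError(
                f"patient {self.patient_id!r}: DQ missing at months {missing}"
            )


def load_registry(path: str | Path) -> dict[str, Regimen]:
    """Load a regimen registry from a YAML file (drug -> dose, interval)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise DqTaperError(f"registry {path}: expected a mapping of drugs")
    registry = {}
    for drug, spec in raw.items():
        try:
            registry[str(drug)] = Regimen(
                drug=str(drug),
                standard_dose=float(spec["standard_dose"]),
                standard_interval=float(spec["standard_interval"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise DqTaperError(
                f"registry {path}: malformed entry for {drug!r}"
            ) from exc
    return registry


def default_registry() -> dict[str, Regimen]:
    """The packaged default registry of standard TNFi regimens.

    Etanercept 25 mg / 3.5 d, adalimumab 40 mg / 14 d, golimumab
    50 mg / 28 d, infliximab 5 mg-per-kg / 56 d.  These are standard
    label regimens; override with :func:`load_registry` if your cohort
    used different full-dose conventions.
    """
    ref = resources.files("dqtaper.data").joinpath("regimens.yaml")
    with resources.as_file(ref) as path:
        return load_registry(path)


def compute_dq(
    actual_dose: float,
    actual_interval: float,
    regimen: Regimen,
) -> float:
    """Dose quotient of one observed regimen against its standard.

    A dose of 0 encodes withdrawal and scores 0 at any interval.
    """
    if not actual_interval > 0:
        raise DqTaperError(
            f"actual_interval must be > 0, got {actual_interval!r}"
        )
    if actual_dose < 0:
        raise DqTaperError(f"actual_dose must be >= 0, got {actual_dose!r}")
    return (
        (actual_dose / regimen.standard_dose)
        * (regimen.standard_interval / actual_interval)
        * 100.0
    )


def build_timeline(
    doses: pd.DataFrame,
    registry: Mapping[str, Regimen],
) -> DqTimeline:
    """DQ timeline for one patient from their dose observations.

    ``doses`` holds columns patient_id, month, drug, actual_dose,
    actual_interval for a single patient, one row per canonical month
    (withdrawal encoded as actual_dose 0).
    """
    pids = doses["patient_id"].unique()
    if len(pids) != 1:
        raise DqTaperError(
            f"build_timeline expects one patient, got {sorted(map(str, pids))}"
        )
    pid = str(pids[0])
    months = doses["month"].to_numpy()
    if len(set(months)) != len(months):
        raise DqTaperError(f"patient {pid!r}: duplicate dose months")
    dq: dict[int, float] = {}
    for row in doses.itertuples(index=False):
        drug = str(row.drug)
        if drug not in registry:
            raise UnknownRegimenError(
                f"patient {pid!r} month {row.month}: drug {drug!r} "
                f"not in regimen registry {sorted(registry)}"
            )
        dq[int(row.month)] = compute_dq(
            float(row.actual_dose), float(row.actual_interval), registry[drug]
        )
    return DqTimeline(patient_id=pid, dq=dq)


def timelines_from_doses(
    doses: pd.DataFrame,
    registry: Mapping[str, Regimen],
) -> dict[str, DqTimeline]:
    """Build a DQ timeline for every patient in a doses table."""
    return {
        str(pid): build_timeline(group, registry)
        for pid, group in doses.groupby("patient_id", sort=True)
    }


def average_dq(timeline: DqTimeline, interval: str) -> float:
    """Interval-average DQ.

    3-month intervals average the two endpoint DQs; the 12-24 month
    interval is the mean of its two half-interval means,
    ``(DQ12 + 2*DQ18 + DQ24) / 4``.
    """
    if interval not in INTERVALS:
        raise DqTaperError(
            f"unknown interval {interval!r}; expected one of {sorted(INTERVALS)}"
        )
    t0, t1 = INTERVALS[interval]
    dq = timeline.dq
    if interval == "I5":
        return (dq[12] + 2.0 * dq[18] + dq[24]) / 4.0
    return (dq[t0] + dq[t1]) / 2.0


def taper_schedule(
    variant: str,
    start_month: int,
) -> dict[int, float]:
    """Planned DQ at each canonical month for one taper track.

    ``start_month`` (3 or 6) is the visit at which the first reduction
    is decided; each phase lasts 3 months, so the reduced dose is the
    one in force during the phase *ending* at the following grid month.
    The grid value at month m is therefore the dose in force over the
    interval ending at m: still 100 at the start month itself, then the
    track levels at the subsequent visits, with the final level
    maintained through month 24.
    """
    if variant not in TAPER_TRACKS:
        raise DqTaperError(
            f"unknown taper variant {variant!r}; expected one of "
            f"{sorted(TAPER_TRACKS)}"
        )
    if start_month not in (3, 6):
        raise DqTaperError(f"start_month must be 3 or 6, got {start_month!r}")
    levels = TAPER_TRACKS[variant]
    planned: dict[int, float] = {}
    for m in CANONICAL_MONTHS:
        if m <= start_month:
            planned[m] = 100.0
        else:
            # Phase index of the phase ending at month m (1-based).
            phase = min((m - start_month + 2) // 3, len(levels))
            planned[m] = levels[phase - 1]
    return planned
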