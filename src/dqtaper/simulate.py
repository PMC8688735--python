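"""Synthetic two-arm tapering/withdrawal cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without patient data:

* a run-in at full dose (DQ 100 at month 0 for everyone), then either
  gradual tapering along a two-thirds or half track or rapid reduction
  to withdrawal (DQ 0 by month 12);
* time-varying confounding: the dose decision at each visit depends on
  the current ASDAS-CRP.  Under the default ``track-hold`` policy a
  planned reduction is *held* with probability ``confounding_strength``
  when ASDAS-CRP is at or above the remission threshold (1.3) at the
  decision visit; under the ``continuous`` policy
  the next DQ is the planned level plus ``confounding_strength`` DQ
  units per ASDAS unit above 2.0 plus Gaussian noise (the regime in
  which the Gaussian treatment model of the weighting stage is
  correctly specified);
* interval-level outcomes with exactly known coefficients: each MRI
  score change is ``intercept + slope * avg_dq + confounder_effect *
  (asdas_start - 2) + patient effect + noise``;
* a relapse indicator drawn from a linear probability in average DQ,
  clipped to [0, 1]; the ASDAS-CRP endpoint is then sampled on the
  matching side of 2.1, so interval status classification reproduces
  the drawn indicator exactly;
* MRI missingness at months 3, 6 and 18 (months 0, 9, 12 and 24 are
  always scanned).

Scores are clipped to instrument bounds (clipping is counted and rare
at the defaults); the parameter-recovery preset disables clipping and
missingness so the true slopes are exactly defined.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, validate_cohort
from .constants import CANONICAL_MONTHS, MRI_SCORES, SCORE_BOUNDS
from .dosing import TAPER_TRACKS, default_registry, taper_schedule
from .errors import DqTaperError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate",
    "generate_paper_shaped",
    "recovery_config",
    "simulate_interval_table",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the study conditions.

    Slopes are per DQ unit.  ``confounding_strength`` is interpreted by
    ``dose_policy`` (see the module docstring).
    """

    n_patients: int = 108
    p_tapering: float = 63.0 / 108.0
    seed: int = 0
    taper_track_probs: dict = field(
        default_factory=lambda: {"two-thirds": 0.5, "half": 0.5}
    )
    taper_start_probs: dict = field(default_factory=lambda: {3: 0.5, 6: 0.5})
    dose_policy: str = "track-hold"
    confounding_strength: float = 0.7
    dose_noise_sd: float = 8.0  # continuous policy only
    slope_sparcc: float = -0.096
    slope_fat: float = 0.0
    slope_erosion: float = -0.010
    slope_backfill: float = -0.0034
    slope_relapse_prob: float = -0.034
    relapse_intercept: float = 1.15
    relapse_asdas_coef: float = 0.08
    intercepts: dict = field(
        default_factory=lambda: {
            "sparcc": 4.0,
            "fat": 1.8,
            "erosion": 2.0,
            "backfill": 1.0,
        }
    )
    confounder_effects: dict = field(
        default_factory=lambda: {
            "sparcc": 0.8,
            "fat": 0.2,
            "erosion": 0.3,
            "backfill": 0.1,
        }
    )
    noise_sd: dict = field(
        default_factory=lambda: {
            "sparcc": 1.2,
            "fat": 0.8,
            "erosion": 0.8,
            "backfill": 0.5,
        }
    )
    cluster_sd: float = 0.4
    mri_missing_prob: float = 0.5
    clip_scores: bool = True

    def validate(self) -> None:
        if self.n_patients < 2:
            raise DqTaperError("n_patients must be >= 2")
        probs = [self.p_tapering, self.mri_missing_prob, *(
            [self.confounding_strength]
            if self.dose_policy == "track-hold"
            else []
        )]
        if any(not 0 <= q <= 1 for q in probs):
            raise DqTaperError("probabilities must lie in [0, 1]")
        if self.dose_policy not in ("track-hold", "continuous"):
            raise DqTaperError(f"unknown dose_policy {self.dose_policy!r}")
        if any(v < 0 for v in self.noise_sd.values()) or self.cluster_sd < 0:
            raise DqTaperError("SDs must be >= 0")

    @property
    def slopes(self) -> dict:
        return {
            "sparcc": self.slope_sparcc,
            "fat": self.slope_fat,
            "erosion": self.slope_erosion,
            "backfill": self.slope_backfill,
        }


@dataclass(frozen=True)
class GroundTruth:
    """The realized true parameters of one generated cohort."""

    seed: int
    n_patients: int
    slopes: dict
    slope_relapse_prob: float
    intercepts: dict
    confounder_effects: dict
    noise_sd: dict
    cluster_sd: float
    dose_policy: str
    confounding_strength: float
    clip_fraction: float
    config: dict

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


# Interval endpoints in simulation order; I5 spans two visit gaps.
_INTERVAL_ENDPOINTS = [(0, 3), (3, 6), (6, 9), (9, 12), (12, 24)]


def _draw_baseline(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Baseline covariates with marginals shaped like the study cohort
    (young, two-thirds male, ~58% AS, ~80% HLA-B27 positive)."""
    age = np.clip(np.round(rng.normal(29.0, 7.0, n)), 16, 70).astype(int)
    duration = np.round(rng.lognormal(np.log(12.0), 0.9, n)).astype(int)
    return pd.DataFrame(
        {
            "sex": np.where(rng.random(n) < 0.67, "male", "female"),
            "diagnosis": np.where(rng.random(n) < 0.58, "AS", "nr-axSpA"),
            "age": age,
            "duration": duration,
            "hla_b27": (rng.random(n) < 0.80).astype(int),
            "smoking": (rng.random(n) < 0.41).astype(int),
        }
    )


def _withdrawal_plan(rng: np.random.Generator) -> dict[int, float]:
    """Rapid-reduction path reaching DQ 0 by month 12."""
    dq6 = rng.choice([66.7, 50.0, 25.0, 0.0], p=[0.2, 0.4, 0.15, 0.25])
    dq9 = 0.0 if dq6 == 0.0 else min(dq6, rng.choice([25.0, 0.0], p=[0.6, 0.4]))
    return {0: 100.0, 3: 100.0, 6: dq6, 9: dq9, 12: 0.0, 18: 0.0, 24: 0.0}


def _next_dq(
    planned: float,
    dq_prev: float,
    asdas_prev: float,
    cfg: SimConfig,
    tapering: bool,
    rng: np.random.Generator,
) -> float:
    if cfg.dose_policy == "continuous":
        return float(
            np.clip(
                planned
                + cfg.confounding_strength * (asdas_prev - 2.0)
                + rng.normal(0.0, cfg.dose_noise_sd),
                0.0,
                100.0,
            )
        )
    # track-hold: a planned reduction is held when the patient is not in
    # deep remission (ASDAS-CRP >= 1.3) at the decision visit.
    if (
        tapering
        and planned < dq_prev
        and asdas_prev >= 1.3
        and rng.random() < cfg.confounding_strength
    ):
        return dq_prev
    return planned


def generate(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate one cohort and its ground truth; reproducible by seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"P{i + 1:04d}" for i in range(n)]
    n_tap = int(round(n * config.p_tapering))
    groups = np.array(["tapering"] * n_tap + ["withdrawal"] * (n - n_tap))
    rng.shuffle(groups)

    base = _draw_baseline(rng, n)
    base.insert(0, "patient_id", ids)
    base.insert(1, "group", groups)
    patients = base[
        [
            "patient_id",
            "group",
            "diagnosis",
            "sex",
            "age",
            "duration",
            "hla_b27",
            "smoking",
        ]
    ]

    registry = default_registry()
    drugs = rng.choice(
        ["etanercept", "adalimumab", "golimumab", "infliximab"],
        size=n,
        p=[0.4, 0.3, 0.15, 0.15],
    )
    tracks = rng.choice(
        list(config.taper_track_probs),
        size=n,
        p=list(config.taper_track_probs.values()),
    )
    starts = rng.choice(
        list(config.taper_start_probs),
        size=n,
        p=list(config.taper_start_probs.values()),
    )

    visit_rows, mri_rows, dose_rows = [], [], []
    clipped = 0
    cells = 0
    for i, pid in enumerate(ids):
        tapering = groups[i] == "tapering"
        plan = (
            taper_schedule(str(tracks[i]), int(starts[i]))
            if tapering
            else _withdrawal_plan(rng)
        )
        asdas = {0: 2.1 + rng.gamma(2.0, 0.65)}
        dq = {0: 100.0}
        b_eff = {s: rng.normal(0.0, config.cluster_sd) for s in MRI_SCORES}
        mri0 = {
            "sparcc": float(np.clip(rng.normal(19.0, 7.0), *SCORE_BOUNDS["sparcc"])),
            "fat": float(np.clip(rng.normal(12.0, 6.0), *SCORE_BOUNDS["fat"])),
            "erosion": float(
                np.clip(rng.normal(11.0, 6.0), *SCORE_BOUNDS["erosion"])
            ),
            "backfill": float(min(rng.poisson(1.0), SCORE_BOUNDS["backfill"][1])),
        }
        series = {s: {0: mri0[s]} for s in MRI_SCORES}

        for t0, t1 in _INTERVAL_ENDPOINTS:
            if t1 == 24:
                # 12-24: two dose decisions (months 18 and 24), both
                # made on the last interval-endpoint assessment.
                dq[18] = _next_dq(
                    plan[18], dq[12], asdas[12], config, tapering, rng
                )
                dq[24] = _next_dq(
                    plan[24], dq[18], asdas[12], config, tapering, rng
                )
                avg = (dq[12] + 2.0 * dq[18] + dq[24]) / 4.0
            else:
                dq[t1] = _next_dq(
                    plan[t1], dq[t0], asdas[t0], config, tapering, rng
                )
                avg = (dq[t0] + dq[t1]) / 2.0

            p_rel = float(
                np.clip(
                    config.relapse_intercept
                    + config.slope_relapse_prob * avg
                    + config.relapse_asdas_coef * (asdas[t0] - 2.1),
                    0.0,
                    1.0,
                )
            )
            relapse = rng.random() < p_rel
            if relapse:
                asdas[t1] = 2.1 + rng.gamma(1.5, 0.4)
            else:
                asdas[t1] = float(np.clip(rng.normal(1.1, 0.45), 0.05, 2.05))

            for s in MRI_SCORES:
                delta = (
                    config.intercepts[s]
                    + config.slopes[s] * avg
                    + config.confounder_effects[s] * (asdas[t0] - 2.0)
                    + b_eff[s]
                    + rng.normal(0.0, config.noise_sd[s])
                )
                if t1 == 24:
                    series[s][18] = series[s][12] + delta / 2.0
                    series[s][24] = series[s][12] + delta
                else:
                    series[s][t1] = series[s][t0] + delta

        if config.clip_scores:
            for s in MRI_SCORES:
                lo, hi = SCORE_BOUNDS[s]
                for m in series[s]:
                    cells += 1
                    v = series[s][m]
                    if v < lo or v > hi:
                        clipped += 1
                        series[s][m] = float(np.clip(v, lo, hi))

        # ASDAS at month 18 (visit only; not an interval endpoint).
        asdas[18] = float(
            max(0.0, (asdas[12] + asdas[24]) / 2.0 + rng.normal(0.0, 0.3))
        )

        for m in CANONICAL_MONTHS:
            a = asdas[m]
            visit_rows.append(
                {
                    "patient_id": pid,
                    "month": m,
                    "asdas_crp": round(a, 3),
                    "asdas_esr": round(max(0.0, a + rng.normal(0.0, 0.25)), 3),
                    "basdai": round(float(np.clip(1.15 * a + rng.normal(0.0, 0.7), 0, 10)), 2),
                    "basfi": round(float(np.clip(0.6 * a - 0.3 + rng.normal(0.0, 0.5), 0, 10)), 2),
                    "crp": round(float(np.exp(1.0 + 0.5 * a + rng.normal(0.0, 0.6))), 2),
                    "esr": round(float(np.exp(1.6 + 0.45 * a + rng.normal(0.0, 0.5))), 1),
                }
            )
            scanned = (
                m not in (3, 6, 18) or rng.random() >= config.mri_missing_prob
            )
            if scanned:
                mri_rows.append(
                    {
                        "patient_id": pid,
                        "month": m,
                        **{s: round(series[s][m], 2) for s in MRI_SCORES},
                        "measured": 1,
                    }
                )
            regimen = registry[str(drugs[i])]
            level = dq[m]
            if level > 0:
                dose_rows.append(
                    {
                        "patient_id": pid,
                        "month": m,
                        "drug": str(drugs[i]),
                        "actual_dose": regimen.standard_dose,
                        "actual_interval": regimen.standard_interval * 100.0 / level,
                    }
                )
            else:
                dose_rows.append(
                    {
                        "patient_id": pid,
                        "month": m,
                        "drug": str(drugs[i]),
                        "actual_dose": 0.0,
                        "actual_interval": regimen.standard_interval,
                    }
                )

    cohort = Cohort(
        patients=patients.reset_index(drop=True),
        visits=pd.DataFrame(visit_rows),
        mri=pd.DataFrame(mri_rows),
        doses=pd.DataFrame(dose_rows),
    )
    if not config.clip_scores:
        # Unclipped scores may leave the instrument ranges; widen the
        # cohort's validation bounds accordingly (recovery preset).
        cohort.score_bounds = {
            s: (-np.inf, np.inf) for s in SCORE_BOUNDS
        }
    validate_cohort(cohort)
    truth = GroundTruth(
        seed=config.seed,
        n_patients=n,
        slopes=config.slopes,
        slope_relapse_prob=config.slope_relapse_prob,
        intercepts=dict(config.intercepts),
        confounder_effects=dict(config.confounder_effects),
        noise_sd=dict(config.noise_sd),
        cluster_sd=config.cluster_sd,
        dose_policy=config.dose_policy,
        confounding_strength=config.confounding_strength,
        clip_fraction=(clipped / cells) if cells else 0.0,
        config={
            **{
                k: v
                for k, v in asdict(config).items()
                if not isinstance(v, dict)
            }
        },
    )
    return cohort, truth


def generate_paper_shaped(seed: int = 0) -> tuple[Cohort, GroundTruth]:
    """Convenience preset: 108 patients, 63 tapering / 45 withdrawal,
    baseline marginals shaped like the study cohort."""
    return generate(SimConfig(seed=seed))


def recovery_config(
    n_patients: int = 400,
    seed: int = 0,
    confounding_strength: float = 6.0,
    mri_missing_prob: float = 0.0,
) -> SimConfig:
    """Parameter-recovery preset: all-tapering arm, continuous dose
    policy (Gaussian treatment model correctly specified), no score
    clipping, no MRI missingness — the regime in which the configured
    slopes are exactly the estimands."""
    return SimConfig(
        n_patients=n_patients,
        p_tapering=1.0,
        seed=seed,
        dose_policy="continuous",
        confounding_strength=confounding_strength,
        dose_noise_sd=10.0,
        mri_missing_prob=mri_missing_prob,
        clip_scores=False,
    )


def simulate_interval_table(
    n_patients: int = 150,
    seed: int = 0,
    confounding: float = 8.0,
    slopes: dict | None = None,
    confounder_effect: float = 1.0,
    noise_sd: float = 1.5,
    cluster_sd: float = 0.5,
    dose_sd: float = 15.0,
) -> tuple[pd.DataFrame, dict]:
    """Interval-level harness with an exactly Gaussian-linear exposure.

    Generates 5 interval records per synthetic patient directly:
    ``avg_dq = 60 - confounding * (asdas_start - 2) + N(0, dose_sd)``
    (clipped-free), outcomes linear in avg_dq and asdas_start with a
    shared patient effect.  Because the treatment assignment is exactly
    the model the weighting stage fits, this isolates the stabilized-
    weighting property (balance, mean weight 1, bias removal) from any
    dose-policy misspecification.  Returns the records plus the truth.
    """
    rng = np.random.default_rng(seed)
    slopes = dict(slopes or {"d_sparcc": -0.096, "d_fat": 0.0, "d_erosion": -0.010})
    n_rec = n_patients * 5
    pid = np.repeat([f"P{i + 1:04d}" for i in range(n_patients)], 5)
    interval_id = np.tile(["I1", "I2", "I3", "I4", "I5"], n_patients)
    base = _draw_baseline(rng, n_patients)
    asdas_start = np.clip(
        rng.normal(2.0, 0.8, n_rec) + np.repeat(rng.normal(0, 0.3, n_patients), 5),
        0.05,
        None,
    )
    avg_dq = (
        60.0
        - confounding * (asdas_start - 2.0)
        - 3.0 * np.repeat(base["hla_b27"].to_numpy(), 5)
        + rng.normal(0.0, dose_sd, n_rec)
    )
    records = pd.DataFrame(
        {
            "patient_id": pid,
            "interval_id": interval_id,
            "avg_dq": avg_dq,
            "asdas_start": asdas_start,
            "sex_male": np.repeat((base["sex"] == "male").astype(int).to_numpy(), 5),
            "age": np.repeat(base["age"].to_numpy(), 5),
            "diagnosis_as": np.repeat(
                (base["diagnosis"] == "AS").astype(int).to_numpy(), 5
            ),
            "duration": np.repeat(base["duration"].to_numpy(), 5),
            "smoking": np.repeat(base["smoking"].to_numpy(), 5),
            "hla_b27": np.repeat(base["hla_b27"].to_numpy(), 5),
        }
    )
    for outcome, slope in slopes.items():
        b = np.repeat(rng.normal(0.0, cluster_sd, n_patients), 5)
        records[outcome] = (
            2.0
            + slope * avg_dq
            + confounder_effect * (asdas_start - 2.0)
            + b
            + rng.normal(0.0, noise_sd, n_rec)
        )
    truth = {
        "slopes": slopes,
        "confounding": confounding,
        "confounder_effect": confounder_effect,
        "noise_sd": noise_sd,
        "cluster_sd": cluster_sd,
        "dose_sd": dose_sd,
        "seed": seed,
    }
    return records, truth
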