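"""Stabilized inverse-probability-of-treatment weights for a continuous
exposure (the interval-average dose quotient).

The exposure model is Gaussian: average DQ is regressed linearly on a
covariate set, and the conditional density of the observed exposure is
evaluated under the fitted mean and (maximum-likelihood) residual SD.
The stabilized weight of an interval record is the ratio of two such
densities::

    SW = f(avg_dq | baseline covariates) / f(avg_dq | baseline covariates
                                              + ASDAS-CRP at interval start)

The numerator conditions on the baseline covariates only (sex, age,
diagnosis, disease duration, smoking, HLA-B27); the denominator adds
the time-varying confounder, ASDAS-CRP at the start of the interval.
Under a correctly specified denominator model the weighted sample
breaks the confounder-exposure association while the stabilized
numerator keeps the weights near 1.

Weights are pointwise per interval by default; a cumulative variant
(product over the patient's intervals up to and including the current
one) is available for sensitivity analysis.  Truncation is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import BASELINE_COVARIATES, INTERVAL_ORDER
from .errors import SingularDesignError, WeightError

__all__ = [
    "TreatmentModel",
    "WeightSet",
    "fit_treatment_model",
    "stabilized_weights",
    "truncate_weights",
    "NUMERATOR_COVARIATES",
    "DENOMINATOR_COVARIATES",
]

NUMERATOR_COVARIATES: tuple[str, ...] = BASELINE_COVARIATES
DENOMINATOR_COVARIATES: tuple[str, ...] = (*BASELINE_COVARIATES, "asdas_start")


@dataclass(frozen=True)
class TreatmentModel:
    """Gaussian exposure model: linear mean plus homoscedastic residual SD.

    ``residual_sd`` is the maximum-likelihood (n-denominator) estimate.
    """

    covariate_names: tuple[str, ...]
    coefficients: np.ndarray  # intercept first, then one per covariate
    residual_sd: float
    n_obs: int

    def mean(self, records: pd.DataFrame) -> np.ndarray:
        """Fitted conditional mean of the exposure for each record."""
        X = _design(records, self.covariate_names)
        return X @ self.coefficients

    def density(self, records: pd.DataFrame, exposure: str = "avg_dq") -> np.ndarray:
        """Gaussian density of the observed exposure under the model."""
        mu = self.mean(records)
        return stats.norm.pdf(records[exposure].to_numpy(), mu, self.residual_sd)


@dataclass
class WeightSet:
    """Stabilized weights plus summary diagnostics."""

    weights: np.ndarray
    numerator_model: TreatmentModel | None = None
    denominator_model: TreatmentModel | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        self.weights = w
        if not self.diagnostics:
            self.diagnostics = summarize_weights(w)


def summarize_weights(w: np.ndarray) -> dict:
    """Mean/min/max and Kish effective sample size of a weight vector."""
    return {
        "mean": float(np.mean(w)),
        "min": float(np.min(w)),
        "max": float(np.max(w)),
        "ess": float(np.sum(w) ** 2 / np.sum(w**2)),
        "n": int(w.size),
    }


def _design(records: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in covariates if c not in records.columns]
    if missing:
        raise SingularDesignError(
            f"covariates {missing} absent from the records table"
        )
    X = np.column_stack(
        [np.ones(len(records))]
        + [records[c].to_numpy(dtype=float) for c in covariates]
    )
    return X


def fit_treatment_model(
    records: pd.DataFrame,
    covariates: tuple[str, ...],
    exposure: str = "avg_dq",
) -> TreatmentModel:
    """Least-squares linear model of the exposure on ``covariates``.

    Raises SingularDesignError (naming the collinear columns) when the
    design is rank deficient.
    """
    covariates = tuple(covariates)
    if len(records) < len(covariates) + 2:
        raise SingularDesignError(
            f"need at least {len(covariates) + 2} records to fit "
            f"{len(covariates)} covariates, got {len(records)}"
        )
    X = _design(records, covariates)
    y = records[exposure].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify offending columns by rank growth.
        names = ("intercept", *covariates)
        bad = []
        r = 0
        for j in range(X.shape[1]):
            nr = np.linalg.matrix_rank(X[:, : j + 1])
            if nr == r:
                bad.append(names[j])
            r = nr
        raise SingularDesignError(
            f"singular design: collinear columns {bad}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    residual_sd = float(np.sqrt(np.mean(resid**2)))
    return TreatmentModel(
        covariate_names=covariates,
        coefficients=beta,
        residual_sd=residual_sd,
        n_obs=len(records),
    )


def stabilized_weights(
    records: pd.DataFrame,
    numerator_covariates: tuple[str, ...] = NUMERATOR_COVARIATES,
    denominator_covariates: tuple[str, ...] = DENOMINATOR_COVARIATES,
    exposure: str = "avg_dq",
    cumulative: bool = False,
) -> WeightSet:
    """Stabilized IPTW weights for every interval record.

    With ``cumulative=True`` the pointwise density ratios are multiplied
    over each patient's intervals up to the current one (time-varying
    MSM convention); the default is the pointwise per-interval ratio.
    """
    num = fit_treatment_model(records, tuple(numerator_covariates), exposure)
    den = fit_treatment_model(records, tuple(denominator_covariates), exposure)
    f_num = num.density(records, exposure)
    f_den = den.density(records, exposure)
    with np.errstate(divide="ignore", invalid="ignore"):
        sw = f_num / f_den
    bad = ~np.isfinite(sw)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        rec = records.iloc[i]
        raise WeightError(
            "weight overflow (denominator density numerically zero) for "
            f"patient {rec.get('patient_id')!r} interval "
            f"{rec.get('interval_id')!r}"
        )
    if cumulative:
        order = {iid: k for k, iid in enumerate(INTERVAL_ORDER)}
        df = pd.DataFrame(
            {
                "patient_id": records["patient_id"].to_numpy(),
                "rank": records["interval_id"].map(order).to_numpy(),
                "sw": sw,
            },
            index=records.index,
        )
        df = df.sort_values(["patient_id", "rank"], kind="mergesort")
        df["sw"] = df.groupby("patient_id")["sw"].cumprod()
        sw = df["sw"].reindex(records.index).to_numpy()
    return WeightSet(weights=sw, numerator_model=num, denominator_model=den)


def truncate_weights(
    weight_set: WeightSet,
    lower_pct: float = 0.0,
    upper_pct: float = 100.0,
) -> WeightSet:
    """Winsorize weights at the given percentiles (standard IPTW hygiene;
    identity at (0, 100), which is the default pipeline setting)."""
    if not (0 <= lower_pct < upper_pct <= 100):
        raise WeightError(
            f"invalid truncation percentiles ({lower_pct}, {upper_pct})"
        )
    w = weight_set.weights
    lo = np.percentile(w, lower_pct)
    hi = np.percentile(w, upper_pct)
    clipped = np.clip(w, lo, hi)
    return WeightSet(
        weights=clipped,
        numerator_model=weight_set.numerator_model,
        denominator_model=weight_set.denominator_model,
    )
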