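"""Time-to-relapse analysis and two-group descriptive statistics.

Relapse timing is interval-grained: a patient's event time is the end
month of their first relapse interval (3, 6, 9, 12 or 24); patients who
never relapse are censored at 24 months.  The survival curve is the
Kaplan-Meier product-limit estimator with Greenwood standard errors and
a Brookmeyer-Crowley (log-log) confidence interval for the median;
group curves are compared with the two-group log-rank test.

Baseline/follow-up group comparisons use the conventional test menu:
Mann-Whitney U (normal approximation, tie- and continuity-corrected) or
Welch's t for continuous variables, chi-square (Yates for 2x2) or
Fisher's exact test (when any expected cell is below 5) for categorical
ones, with medians [IQR] or mean +/- SE reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

from .constants import INTERVAL_ORDER
from .errors import DqTaperError

__all__ = [
    "RelapseTimes",
    "KmCurve",
    "TwoGroupComparison",
    "relapse_times",
    "relapse_rate",
    "km_fit",
    "logrank",
    "compare_groups",
    "describe_table",
]


@dataclass(frozen=True)
class KmCurve:
    """Kaplan-Meier curve with Greenwood SEs and median (95% CI)."""

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    median: float  # inf when not reached
    median_ci95: tuple[float, float]
    n_subjects: int
    n_events: int


@dataclass(frozen=True)
class TwoGroupComparison:
    """One Table-1 style row: the test used, its statistic and p-value,
    and a per-group textual summary."""

    variable: str
    test: str
    statistic: float
    p: float
    summaries: dict[str, str]


def relapse_times(records: pd.DataFrame) -> pd.DataFrame:
    """Per-patient first-relapse time from the intervals table.

    Returns columns patient_id, time (months), event (1 = relapsed,
    0 = censored at 24); the group column is carried through when
    present.
    """
    order = {iid: k for k, iid in enumerate(INTERVAL_ORDER)}
    df = records.sort_values(
        ["patient_id", "interval_id"],
        key=lambda s: s.map(order) if s.name == "interval_id" else s,
        kind="mergesort",
    )
    rows = []
    for pid, grp in df.groupby("patient_id", sort=True):
        relapsed = grp.loc[grp["status"] == "relapse"]
        if len(relapsed):
            time = int(relapsed.iloc[0]["t_end"])
            event = 1
        else:
            time, event = 24, 0
        row = {"patient_id": str(pid), "time": time, "event": event}
        if "group" in grp.columns:
            row["group"] = grp.iloc[0]["group"]
        rows.append(row)
    return pd.DataFrame(rows)


def relapse_rate(records: pd.DataFrame, horizon_months: int) -> float:
    """Percent of patients with >= 1 relapse interval ending by the
    horizon, rounded to 1 decimal (the convention used for printed
    rates)."""
    if len(records) == 0 or "patient_id" not in records.columns:
        raise DqTaperError("relapse_rate: empty group")
    n = records["patient_id"].nunique()
    hit = records.loc[
        (records["status"] == "relapse") & (records["t_end"] <= horizon_months),
        "patient_id",
    ].nunique()
    return round(100.0 * hit / n, 1)


def km_fit(times, events) -> KmCurve:
    """Product-limit estimator with Greenwood variance and
    Brookmeyer-Crowley (log-log) median CI."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise DqTaperError("km_fit: no subjects")
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_["KM_estimate"]
    event_times = surv.index.to_numpy(dtype=float)
    s = surv.to_numpy(dtype=float)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i)).
    tab = kmf.event_table
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = tab["observed"] / (
            tab["at_risk"] * (tab["at_risk"] - tab["observed"])
        )
    cum = terms.replace([np.inf, -np.inf], np.nan).fillna(0.0).cumsum()
    se = s * np.sqrt(cum.to_numpy(dtype=float))
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo = float(ci.iloc[0, 0])
    hi = float(ci.iloc[0, 1])
    return KmCurve(
        event_times=event_times,
        survival=s,
        greenwood_se=se,
        median=median,
        median_ci95=(lo, hi),
        n_subjects=int(t.size),
        n_events=int(e.sum()),
    )


def logrank(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise DqTaperError(
            f"logrank requires exactly 2 groups, got {levels.size}"
        )
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() == 0:
        raise DqTaperError("logrank requires at least one event")
    mask = g == levels[0]
    res = logrank_test(t[mask], t[~mask], e[mask], e[~mask])
    return float(res.test_statistic), float(res.p_value)


def _is_binary(series: pd.Series) -> bool:
    vals = series.dropna().unique()
    return len(vals) <= 2 and not np.issubdtype(series.dtype, np.floating)


def compare_groups(
    data: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    test: str = "auto",
) -> TwoGroupComparison:
    """Two-group comparison of one variable.

    ``test`` may be ``auto`` (Mann-Whitney for continuous, chi-square/
    Fisher for categorical), or an explicit ``mann_whitney``, ``t_test``,
    ``chi_square`` or ``fisher_exact``.
    """
    df = data[[group_col, variable]].dropna()
    if df.empty:
        raise DqTaperError(f"variable {variable!r}: no non-missing values")
    levels = sorted(df[group_col].unique())
    if len(levels) != 2:
        raise DqTaperError(
            f"compare_groups requires 2 groups, got {levels}"
        )
    a = df.loc[df[group_col] == levels[0], variable]
    b = df.loc[df[group_col] == levels[1], variable]

    categorical = df[variable].dtype == object or _is_binary(df[variable])
    if test == "auto":
        test = "categorical" if categorical else "mann_whitney"

    if test in ("chi_square", "fisher_exact", "categorical"):
        table = pd.crosstab(df[group_col], df[variable]).to_numpy()
        expected = stats.contingency.expected_freq(table)
        if test == "fisher_exact" or (
            test == "categorical"
            and table.shape == (2, 2)
            and (expected < 5).any()
        ):
            if table.shape != (2, 2):
                raise DqTaperError(
                    f"Fisher's exact test needs a 2x2 table for {variable!r}"
                )
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            name, statistic = "fisher_exact", float(odds)
        else:
            chi2, p, _, _ = stats.chi2_contingency(
                table, correction=(table.shape == (2, 2))
            )
            name, statistic = "chi_square", float(chi2)
        summaries = {
            str(lvl): _cat_summary(df.loc[df[group_col] == lvl, variable])
            for lvl in levels
        }
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        name, statistic, p = "mann_whitney", float(res.statistic), float(res.pvalue)
        summaries = {str(lvl): _median_iqr(v) for lvl, v in ((levels[0], a), (levels[1], b))}
    elif test == "t_test":
        res = stats.ttest_ind(a, b, equal_var=False)
        name, statistic, p = "t_test", float(res.statistic), float(res.pvalue)
        summaries = {str(lvl): _mean_se(v) for lvl, v in ((levels[0], a), (levels[1], b))}
    else:
        raise DqTaperError(f"unknown test {test!r}")
    return TwoGroupComparison(
        variable=variable,
        test=name,
        statistic=statistic,
        p=float(p),
        summaries=summaries,
    )


def _median_iqr(v: pd.Series) -> str:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.2f} [{q1:.2f}, {q3:.2f}]"


def _mean_se(v: pd.Series) -> str:
    se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else float("nan")
    return f"{v.mean():.2f} ± {se:.2f}"


def _cat_summary(v: pd.Series) -> str:
    counts = v.value_counts().sort_index()
    total = counts.sum()
    return "; ".join(
        f"{lvl}: {cnt} ({100.0 * cnt / total:.1f}%)"
        for lvl, cnt in counts.items()
    )


def describe_table(
    data: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Table-1 style summary: one row per variable with per-group
    summaries, the test used and its p-value."""
    rows = []
    levels = sorted(data[group_col].dropna().unique())
    for var in variables:
        cmp = compare_groups(data, var, group_col=group_col)
        row = {"variable": var, "test": cmp.test, "p": cmp.p}
        for lvl in levels:
            row[str(lvl)] = cmp.summaries.get(str(lvl), "")
        rows.append(row)
    return pd.DataFrame(rows)
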