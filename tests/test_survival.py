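import math

import numpy as np
import pandas as pd
import pytest

from dqtaper.errors import DqTaperError
from dqtaper.survival import (
    compare_groups,
    describe_table,
    km_fit,
    logrank,
    relapse_rate,
    relapse_times,
)


def _interval_records(status_by_patient, group="tapering"):
    """Build a minimal intervals table from per-patient status lists."""
    bounds = [(0, 3), (3, 6), (6, 9), (9, 12), (12, 24)]
    rows = []
    for pid, statuses in status_by_patient.items():
        for (t0, t1), s, iid in zip(
            bounds, statuses, ["I1", "I2", "I3", "I4", "I5"]
        ):
            rows.append(
                {
                    "patient_id": pid,
                    "interval_id": iid,
                    "t_start": t0,
                    "t_end": t1,
                    "status": s,
                    "group": group,
                }
            )
    return pd.DataFrame(rows)


R, X = "response", "relapse"


class TestRelapseTimes:
    def test_never_relapsed_censored_at_24(self):
        rel = relapse_times(_interval_records({"P1": [R] * 5}))
        assert rel.iloc[0].time == 24 and rel.iloc[0].event == 0

    def test_single_relapse_in_second_interval(self):
        rel = relapse_times(_interval_records({"P1": [R, X, R, R, R]}))
        assert rel.iloc[0].time == 6 and rel.iloc[0].event == 1

    def test_first_relapse_wins(self):
        rel = relapse_times(_interval_records({"P1": [X, R, R, R, X]}))
        assert rel.iloc[0].time == 3 and rel.iloc[0].event == 1


class TestRelapseRate:
    def test_printed_count_12_month_rate(self):
        # 11 relapsers by month 12 among 63 patients
        statuses = {
            f"P{i}": ([R, X, R, R, R] if i < 11 else [R] * 5)
            for i in range(63)
        }
        assert relapse_rate(_interval_records(statuses), 12) == 17.5

    def test_printed_count_24_month_rate(self):
        # 19 of 63 never relapse; the rest relapse in the final interval
        statuses = {
            f"P{i}": ([R] * 5 if i < 19 else [R, R, R, R, X])
            for i in range(63)
        }
        assert relapse_rate(_interval_records(statuses), 24) == 69.8

    def test_no_relapsers_gives_zero(self):
        statuses = {f"P{i}": [R] * 5 for i in range(10)}
        assert relapse_rate(_interval_records(statuses), 24) == 0.0

    def test_complement_identity_at_horizon_24(self):
        rng = np.random.default_rng(0)
        statuses = {
            f"P{i}": [
                X if rng.random() < 0.3 else R for _ in range(5)
            ]
            for i in range(40)
        }
        rec = _interval_records(statuses)
        never = sum(all(s == R for s in v) for v in statuses.values())
        assert relapse_rate(rec, 24) == pytest.approx(
            round(100 - 100.0 * never / 40, 1)
        )

    def test_empty_group_rejected(self):
        with pytest.raises(DqTaperError):
            relapse_rate(_interval_records({}), 12)


class TestKaplanMeier:
    def test_ten_subject_fixture_matches_hand_computed_table(self):
        times = [1, 2, 2, 4, 5, 6, 8, 9, 9, 10]
        events = [1, 1, 1, 0, 1, 0, 1, 1, 0, 1]
        curve = km_fit(times, events)
        # hand-computed product-limit:
        # t=1: 9/10; t=2: 9/10*7/9; t=5: *5/6; t=8: *3/4; t=9: *2/3; t=10: 0
        expected = {
            1: 9 / 10,
            2: 9 / 10 * 7 / 9,
            5: 9 / 10 * 7 / 9 * 5 / 6,
            8: 9 / 10 * 7 / 9 * 5 / 6 * 3 / 4,
            9: 9 / 10 * 7 / 9 * 5 / 6 * 3 / 4 * 2 / 3,
            10: 0.0,
        }
        got = dict(zip(curve.event_times, curve.survival))
        for t, s in expected.items():
            assert got[t] == pytest.approx(s, abs=1e-12)
        assert curve.median == 8  # smallest t with S(t) <= 0.5
        assert curve.n_events == 7

    def test_no_censoring_reproduces_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.integers(1, 15, 25)
        curve = km_fit(times, np.ones(25, dtype=int))
        for t, s in zip(curve.event_times, curve.survival):
            if t > 0:
                assert s == pytest.approx(np.mean(times > t))
        # median equals the sample median event time
        assert curve.median == np.percentile(times, 50, method="inverted_cdf")

    def test_all_censored_curve_stays_at_one(self):
        curve = km_fit([24] * 8, [0] * 8)
        assert np.allclose(curve.survival, 1.0)
        assert math.isinf(curve.median)  # not reached

    def test_greenwood_se_zero_before_events_and_positive_after(self):
        curve = km_fit([5, 5, 9, 24, 24], [1, 1, 1, 0, 0])
        by_t = dict(zip(curve.event_times, curve.greenwood_se))
        assert by_t[0.0] == pytest.approx(0.0)
        assert by_t[5.0] > 0


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [3, 6, 9, 12, 24, 3, 6, 9, 12, 24]
        events = [1, 1, 1, 0, 0, 1, 1, 1, 0, 0]
        group = ["a"] * 5 + ["b"] * 5
        chi2, p = logrank(times, events, group)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_is_highly_significant(self):
        times = [3, 3, 3, 3, 6, 6, 6, 6] + [24] * 8
        events = [1] * 8 + [0] * 8
        group = ["a"] * 8 + ["b"] * 8
        chi2, p = logrank(times, events, group)
        assert p < 0.001

    def test_group_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        times = rng.integers(1, 25, 30)
        events = rng.integers(0, 2, 30)
        group = np.where(rng.random(30) < 0.5, "a", "b")
        chi2_a, p_a = logrank(times, events, group)
        swapped = np.where(group == "a", "b", "a")
        chi2_b, p_b = logrank(times, events, swapped)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)
        assert p_a == pytest.approx(p_b, rel=1e-12)

    def test_asymptotic_p_consistent_with_permutation_oracle(self):
        rng = np.random.default_rng(3)
        times = np.concatenate([rng.integers(2, 10, 15),
                                rng.integers(5, 20, 15)])
        events = np.ones(30, dtype=int)
        group = np.array(["a"] * 15 + ["b"] * 15)
        chi2, p = logrank(times, events, group)
        n_perm, hits = 400, 0
        for _ in range(n_perm):
            perm = rng.permutation(group)
            c, _ = logrank(times, events, perm)
            hits += c >= chi2
        p_perm = hits / n_perm
        assert p == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.02)


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by exact hypergeometric enumeration (integers)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k)
               for k in range(lo, hi + 1)}
    obs = weights[a]
    total = sum(weights.values())
    return sum(v for v in weights.values() if v <= obs) / total


class TestCompareGroups:
    def test_fisher_on_small_table_matches_enumeration(self):
        df = pd.DataFrame(
            {
                "group": ["g1"] * 4 + ["g2"] * 4,
                "flag": [1, 1, 1, 0, 1, 0, 0, 0],
            }
        )
        cmp = compare_groups(df, "flag")
        assert cmp.test == "fisher_exact"
        assert cmp.p == pytest.approx(
            fisher_enumeration_oracle([[3, 1], [1, 3]]), abs=1e-12
        )

    def test_fisher_matches_enumeration_on_all_small_tables(self):
        from scipy.stats import fisher_exact

        for n in range(2, 16):
            for r1 in range(n + 1):
                for c1 in range(n + 1):
                    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
                    for a in range(lo, hi + 1):
                        tab = [[a, r1 - a], [c1 - a, n - r1 - c1 + a]]
                        _, p = fisher_exact(tab)
                        assert p == pytest.approx(
                            fisher_enumeration_oracle(tab), abs=1e-10
                        ), tab

    def test_identical_groups_chi_square_p_near_one(self):
        df = pd.DataFrame(
            {
                "group": ["g1"] * 40 + ["g2"] * 40,
                "flag": ([0] * 20 + [1] * 20) * 2,
            }
        )
        cmp = compare_groups(df, "flag")
        assert cmp.test == "chi_square"
        assert cmp.p == pytest.approx(1.0, abs=0.05)

    def test_positivity_rate_summary_from_printed_counts(self):
        # 29 of 39 positive in one group, 24 of 24 in the other
        df = pd.DataFrame(
            {
                "group": ["response"] * 39 + ["relapse"] * 24,
                "hla_b27": [1] * 29 + [0] * 10 + [1] * 24,
            }
        )
        cmp = compare_groups(df, "hla_b27")
        assert "74.4%" in cmp.summaries["response"]
        assert "100.0%" in cmp.summaries["relapse"]
        assert cmp.p < 0.05

    def test_continuous_defaults_to_mann_whitney_with_median_iqr(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "group": ["g1"] * 30 + ["g2"] * 30,
                "age": np.concatenate(
                    [rng.normal(28, 5, 30), rng.normal(34, 5, 30)]
                ),
            }
        )
        cmp = compare_groups(df, "age")
        assert cmp.test == "mann_whitney"
        assert "[" in cmp.summaries["g1"]
        assert cmp.p < 0.05

    def test_welch_t_reports_mean_se(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "group": ["g1"] * 25 + ["g2"] * 25,
                "crp": np.concatenate(
                    [rng.normal(10, 3, 25), rng.normal(10, 8, 25)]
                ),
            }
        )
        cmp = compare_groups(df, "crp", test="t_test")
        assert cmp.test == "t_test"
        assert "±" in cmp.summaries["g1"]

    def test_describe_table_has_row_per_variable(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "group": np.where(rng.random(50) < 0.5, "g1", "g2"),
                "age": rng.normal(30, 5, 50),
                "hla_b27": rng.integers(0, 2, 50),
            }
        )
        table = describe_table(df, ["age", "hla_b27"])
        assert list(table.variable) == ["age", "hla_b27"]
        assert {"g1", "g2"} <= set(table.columns)
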