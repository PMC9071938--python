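from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from pddc.phantom import CohortSpec, make_cohort
from pddc.stats import (
    ContingencyTable2x2,
    GroupSample,
    association_test,
    chi_square,
    cohort_report,
    fisher_exact,
    positivity_rates,
    rank_sum,
    report_to_markdown,
    t_test,
)
from pddc.stats import TestReport as StatReport


def _welch_oracle(x, y):
    """Direct evaluation of the Welch statistic and Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return t, df


def _chi2_oracle(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration over the margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


class TestTTest:
    def test_identical_samples_null(self):
        x = GroupSample("a", [1.0, 2.0, 3.0])
        rep = t_test(x, GroupSample("b", [1.0, 2.0, 3.0]))
        assert rep.statistic == 0.0
        assert rep.p_value == 1.0
        assert not rep.reject

    def test_clear_separation_rejects(self):
        rep = t_test(GroupSample("a", [1, 2, 3]), GroupSample("b", [11, 12, 13]))
        assert abs(rep.statistic) > 5
        assert rep.p_value < 0.01
        assert rep.reject

    def test_welch_matches_direct_formula(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.4, 2.5, 40)
        rep = t_test(GroupSample("x", x), GroupSample("y", y), variant="welch")
        t, df = _welch_oracle(x, y)
        assert abs(rep.statistic - t) < 1e-10
        assert abs(rep.df - df) < 1e-8

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            t_test(GroupSample("a", [1.0]), GroupSample("b", [1.0, 2.0]))

    def test_power_at_reported_group_parameters(self):
        """Group means/SDs like the lacune-count summaries (2.400 +/- 3.358 vs
        0.672 +/- 1.252, n=30) give a Welch test that rejects in the majority
        of replicates."""
        rng = np.random.default_rng(77)
        rejections = 0
        for _ in range(1000):
            x = rng.normal(2.400, 3.358, 30)
            y = rng.normal(0.672, 1.252, 30)
            rejections += t_test(GroupSample("c", x), GroupSample("k", y)).reject
        assert rejections / 1000 > 0.5


class TestChiSquareFisher:
    def test_chi_square_matches_hand_formula_on_study_table(self):
        rep = chi_square(ContingencyTable2x2(14, 16, 4, 26))
        assert abs(rep.statistic - 7.937) < 5e-4
        assert abs(rep.statistic - _chi2_oracle(14, 16, 4, 26)) < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_chi_square_matches_hand_formula_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(5, 40, size=4)
        rep = chi_square(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
        assert abs(rep.statistic - _chi2_oracle(a, b, c, d)) < 1e-10

    def test_proportional_rows_give_zero(self):
        rep = chi_square(ContingencyTable2x2(10, 20, 5, 10))
        assert abs(rep.statistic) < 1e-12

    def test_fisher_small_table(self):
        rep = fisher_exact(ContingencyTable2x2(2, 0, 0, 2))
        assert abs(rep.p_value - 1 / 3) < 1e-12

    @pytest.mark.parametrize("seed", range(8))
    def test_fisher_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b, c, d = (int(v) for v in rng.integers(1, 11, size=4))
        rep = fisher_exact(ContingencyTable2x2(a, b, c, d))
        assert abs(rep.p_value - _fisher_oracle(a, b, c, d)) < 1e-9

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square(ContingencyTable2x2(0, 5, 0, 5))

    def test_low_expected_cells_fall_back_to_fisher(self):
        rep = association_test(ContingencyTable2x2(2, 8, 1, 9))
        assert rep.test_name == "fisher exact"
        rep2 = association_test(ContingencyTable2x2(14, 16, 4, 26))
        assert rep2.test_name.startswith("chi-square")


class TestRankSum:
    def test_identical_distributions_p_one(self):
        rep = rank_sum(GroupSample("a", [1, 2, 3]), GroupSample("b", [1, 2, 3]))
        assert rep.p_value == 1.0

    def test_most_extreme_ranking_exact(self):
        rep = rank_sum(GroupSample("a", [1.0, 2.0]), GroupSample("b", [10.0, 20.0]))
        assert abs(rep.p_value - 1 / 3) < 1e-12
        assert rep.extra["exact"]

    def test_exact_p_matches_manual_enumeration(self):
        x = np.array([1.3, 2.1, 4.0])
        y = np.array([0.5, 3.2, 5.1, 6.0])
        rep = rank_sum(GroupSample("x", x), GroupSample("y", y))
        pooled = np.concatenate([x, y])
        ranks = pooled.argsort().argsort() + 1
        obs = ranks[:3].sum()
        null = [sum(c) for c in combinations(ranks, 3)]
        mean = np.mean(null)
        p_manual = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-9 for s in null])
        assert abs(rep.p_value - p_manual) < 1e-12

    def test_exact_and_asymptotic_agree_at_n10(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10) + 0.3
        exact = rank_sum(GroupSample("x", x), GroupSample("y", y))
        from scipy.stats import mannwhitneyu

        approx = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert exact.extra["exact"]
        assert abs(exact.p_value - approx.pvalue) < 0.02


class TestPositivityRates:
    @pytest.mark.parametrize(
        "positives,n,expected", [(14, 30, 47), (4, 30, 13), (0, 30, 0), (15, 30, 50)]
    )
    def test_integer_percent_rounding(self, positives, n, expected):
        tab = ContingencyTable2x2(positives, n - positives, 1, 29)
        assert positivity_rates(tab)["group1_rate_percent"] == expected

    def test_total_positives(self):
        rates = positivity_rates(ContingencyTable2x2(14, 16, 4, 26))
        assert rates["total_positive"] == 18

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            positivity_rates(ContingencyTable2x2(0, 0, 4, 26))


class TestCohortReport:
    def test_synthetic_cohort_report_complete(self):
        _, table = make_cohort(CohortSpec(n_per_group=30, seed=5))
        report = cohort_report(table)
        for block in (
            "lacunar_infarctions", "cmb_positivity", "cmb_counts",
            "vertebral_dominance", "basilar_morphology",
        ):
            assert block in report
            assert "p_value" in report[block]
        md = report_to_markdown(report)
        assert "cmb_positivity" in md

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        half = pd.DataFrame(
            {
                "lacune_count": rng.poisson(1.5, 30),
                "cmb_count": rng.poisson(1.0, 30),
                "dominant_side": rng.choice(["left", "none"], 30),
            }
        )
        table = pd.concat(
            [half.assign(group="case"), half.assign(group="control")],
            ignore_index=True,
        )
        table["cmb_positive"] = table["cmb_count"] > 0
        report = cohort_report(table)
        for block in ("lacunar_infarctions", "cmb_positivity", "cmb_counts",
                      "vertebral_dominance"):
            assert report[block]["decision"] == "fail to reject"

    def test_missing_columns_listed(self):
        with pytest.raises(ValueError, match="lacune_count"):
            cohort_report(pd.DataFrame({"group": ["case", "control"]}))


def test_decision_is_pure_function_of_p():
    rep = StatReport("x", 1.0, 1.0, 0.049)
    assert rep.reject
    rep2 = StatReport("x", 1.0, 1.0, 0.051)
    assert not rep2.reject
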