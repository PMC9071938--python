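"""Two-group cohort statistics: t-tests, chi-square / Fisher, rank-sum.

The layer mirrors a clinical two-group comparison: measurement data are
summarized as mean +/- SD and compared with an independent-sample t-test
(Welch by default, since group variances are rarely equal); enumeration
data (positivity, dominance) are compared with the chi-square test, falling
back to Fisher's exact method when any expected cell is below 5; ranked data
use the Wilcoxon rank-sum test (exact enumeration for small samples without
ties, normal approximation otherwise).  All decisions are taken at
alpha = 0.05 and no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "ContingencyTable2x2",
    "TestReport",
    "t_test",
    "chi_square",
    "fisher_exact",
    "association_test",
    "rank_sum",
    "positivity_rates",
    "cohort_report",
    "report_to_markdown",
]

ALPHA_DEFAULT = 0.05


@dataclass
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("group sample must be 1-dimensional")

    @property
    def n(self) -> int:
        return len(self.values)

    def summary(self) -> str:
        return f"{self.values.mean():.3f} ± {self.values.std(ddof=1):.3f}"


@dataclass
class ContingencyTable2x2:
    """Rows = groups, columns = (positive, negative)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cells must be non-negative integers")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def row_totals(self) -> tuple[int, int]:
        return self.a + self.b, self.c + self.d

    def expected(self) -> np.ndarray:
        t = self.array
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


@dataclass
class TestReport:
    test_name: str
    statistic: float
    df: float | None
    p_value: float
    alpha: float = ALPHA_DEFAULT
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha

    @property
    def decision(self) -> str:
        return "reject" if self.reject else "fail to reject"


def t_test(
    x: GroupSample, y: GroupSample, variant: str = "welch", alpha: float = ALPHA_DEFAULT
) -> TestReport:
    """Independent-sample t-test (Welch default, Student by flag)."""
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    if x.n < 2 or y.n < 2:
        raise ValueError("each group needs n >= 2")
    if x.values.std(ddof=1) == 0 and y.values.std(ddof=1) == 0 and (
        x.values.mean() == y.values.mean()
    ):
        return TestReport(f"{variant} t", 0.0, float(x.n + y.n - 2), 1.0, alpha)
    res = sps.ttest_ind(x.values, y.values, equal_var=(variant == "student"))
    return TestReport(
        f"{variant} t",
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
        alpha,
        extra={"summary_x": x.summary(), "summary_y": y.summary()},
    )


def chi_square(
    tab: ContingencyTable2x2, yates: bool = False, alpha: float = ALPHA_DEFAULT
) -> TestReport:
    """Pearson chi-square on a 2x2 table, optional continuity correction."""
    t = tab.array
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, df, _ = sps.chi2_contingency(t, correction=yates)
    return TestReport("chi-square" + (" (Yates)" if yates else ""),
                      float(stat), float(df), float(p), alpha)


def fisher_exact(tab: ContingencyTable2x2, alpha: float = ALPHA_DEFAULT) -> TestReport:
    """Fisher's exact probability method, two-sided."""
    t = tab.array
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestReport("fisher exact", float(odds), None, float(p), alpha)


def association_test(tab: ContingencyTable2x2, alpha: float = ALPHA_DEFAULT) -> TestReport:
    """Chi-square, or Fisher's exact when any expected cell is below 5."""
    if tab.expected().min() < 5:
        return fisher_exact(tab, alpha)
    return chi_square(tab, alpha=alpha)


def rank_sum(x: GroupSample, y: GroupSample, alpha: float = ALPHA_DEFAULT) -> TestReport:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) with midrank ties.

    Exact null enumeration when both groups have n <= 10 and the pooled
    sample is tie-free; normal approximation otherwise.
    """
    if x.n < 1 or y.n < 1:
        raise ValueError("each group needs n >= 1")
    pooled = np.concatenate([x.values, y.values])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = x.n <= 10 and y.n <= 10 and not has_ties
    res = sps.mannwhitneyu(
        x.values, y.values, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return TestReport(
        "rank sum" + (" (exact)" if exact else ""),
        float(res.statistic), None, float(min(res.pvalue, 1.0)), alpha,
        extra={"exact": exact},
    )


def _round_half_up_percent(fraction: float) -> int:
    return int(np.floor(100.0 * fraction + 0.5))


def positivity_rates(tab: ContingencyTable2x2) -> dict:
    """Per-group positivity rates as integer percents (round-half-up)."""
    n1, n2 = tab.row_totals
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    return {
        "group1_positive": tab.a,
        "group1_n": n1,
        "group1_rate_percent": _round_half_up_percent(tab.a / n1),
        "group2_positive": tab.c,
        "group2_n": n2,
        "group2_rate_percent": _round_half_up_percent(tab.c / n2),
        "total_positive": tab.a + tab.c,
    }


REQUIRED_COHORT_COLUMNS = (
    "group", "lacune_count", "cmb_count", "cmb_positive", "dominant_side",
)


def cohort_report(table: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> dict:
    """Full two-group report: counts, mean +/- SD, tests and alpha decisions.

    Expects the cohort table produced by the phantom cohort generator (or an
    equivalent CSV) with case/control groups.  Returns a JSON-serializable
    dict with one block per analysis.
    """
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    groups = sorted(table["group"].unique(), key=lambda g: g != "case")
    if len(groups) != 2:
        raise ValueError("cohort table must contain exactly two groups")
    g1, g2 = groups
    t1 = table[table["group"] == g1]
    t2 = table[table["group"] == g2]

    def _report(rep: TestReport) -> dict:
        return {
            "test": rep.test_name,
            "statistic": rep.statistic,
            "df": rep.df,
            "p_value": rep.p_value,
            "decision": rep.decision,
        }

    def _assoc(tab: ContingencyTable2x2) -> dict:
        t = tab.array
        if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
            # no variation in the outcome: no association is testable
            return _report(TestReport("degenerate (zero margin)", 0.0, None, 1.0, alpha))
        return _report(association_test(tab, alpha=alpha))

    blocks: dict = {"groups": {g1: len(t1), g2: len(t2)}, "alpha": alpha}

    lac1 = GroupSample(g1, t1["lacune_count"].to_numpy(float))
    lac2 = GroupSample(g2, t2["lacune_count"].to_numpy(float))
    blocks["lacunar_infarctions"] = {
        f"{g1}_mean_sd": lac1.summary(),
        f"{g2}_mean_sd": lac2.summary(),
        **_report(t_test(lac1, lac2, alpha=alpha)),
    }

    tab = ContingencyTable2x2(
        int(t1["cmb_positive"].sum()), int((~t1["cmb_positive"].astype(bool)).sum()),
        int(t2["cmb_positive"].sum()), int((~t2["cmb_positive"].astype(bool)).sum()),
    )
    blocks["cmb_positivity"] = {
        **positivity_rates(tab),
        **_assoc(tab),
    }

    cmb1 = GroupSample(g1, t1["cmb_count"].to_numpy(float))
    cmb2 = GroupSample(g2, t2["cmb_count"].to_numpy(float))
    blocks["cmb_counts"] = {
        f"{g1}_mean_sd": cmb1.summary(),
        f"{g2}_mean_sd": cmb2.summary(),
        **_report(t_test(cmb1, cmb2, alpha=alpha)),
    }

    dom = ContingencyTable2x2(
        int((t1["dominant_side"] != "none").sum()),
        int((t1["dominant_side"] == "none").sum()),
        int((t2["dominant_side"] != "none").sum()),
        int((t2["dominant_side"] == "none").sum()),
    )
    blocks["vertebral_dominance"] = {
        f"{g1}_dominant": dom.a,
        f"{g2}_dominant": dom.c,
        f"{g1}_left": int((t1["dominant_side"] == "left").sum()),
        f"{g1}_right": int((t1["dominant_side"] == "right").sum()),
        f"{g2}_left": int((t2["dominant_side"] == "left").sum()),
        f"{g2}_right": int((t2["dominant_side"] == "right").sum()),
        **_assoc(dom),
    }

    if "curvature_type" in table.columns:
        cur = ContingencyTable2x2(
            int((t1["curvature_type"] != "normal").sum()),
            int((t1["curvature_type"] == "normal").sum()),
            int((t2["curvature_type"] != "normal").sum()),
            int((t2["curvature_type"] == "normal").sum()),
        )
        blocks["basilar_morphology"] = {
            f"{g1}_abnormal": cur.a,
            f"{g2}_abnormal": cur.c,
            **_assoc(cur),
        }

    blocks["footer"] = "No multiple-testing correction applied."
    return blocks


def report_to_markdown(blocks: dict) -> str:
    lines = ["# Cohort report", ""]
    for name, block in blocks.items():
        if name in ("alpha", "footer"):
            continue
        lines.append(f"## {name}")
        if isinstance(block, dict):
            for key, val in block.items():
                lines.append(f"- {key}: {val}")
        else:
            lines.append(f"- {block}")
        lines.append("")
    lines.append(f"alpha = {blocks.get('alpha', ALPHA_DEFAULT)}; {blocks.get('footer', '')}")
    return "\n".join(lines)
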