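"""Group-comparison statistics with a normality-based decision rule.

The dispatch rule mirrors standard practice in the source protocols: each
group is checked for normality (Shapiro-Wilk at alpha = 0.05); if every
group passes, a parametric test is used (two-tailed t for two groups,
one-way ANOVA with Tukey's HSD for more), otherwise a non-parametric one
(Mann-Whitney U, Wilcoxon signed-rank for paired designs, Kruskal-Wallis
for multi-group).  Specific tests can be forced for analyses whose
protocol names one (e.g. Mann-Whitney for engulfment ratios,
Kolmogorov-Smirnov for mEPSC distributions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare", "ks_compare", "bonferroni"]

SHAPIRO_ALPHA = 0.05


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    iqr: float


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    group_summaries: list[GroupSummary]
    paired: bool = False
    correction: str = "none"
    pairwise: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


def _summaries(groups: list[np.ndarray]) -> list[GroupSummary]:
    out = []
    for g in groups:
        q1, q3 = np.percentile(g, [25, 75])
        out.append(GroupSummary(len(g), float(np.mean(g)),
                                float(np.std(g, ddof=1)) if len(g) > 1 else 0.0,
                                float(np.median(g)), float(q3 - q1)))
    return out


def _all_normal(groups: list[np.ndarray]) -> bool:
    for g in groups:
        if len(g) < 3 or np.ptp(g) == 0:
            return False
        if sps.shapiro(g).pvalue < SHAPIRO_ALPHA:
            return False
    return True


def compare(
    groups: list[np.ndarray] | dict[str, np.ndarray],
    design: str = "unpaired",
    rule: str = "auto",
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-tailed comparison of two or more groups.

    ``design`` is ``"unpaired"``, ``"paired"`` (two equal-length groups),
    or ``"multi"`` (>= 2 groups, multiple-comparison corrected).
    ``rule="auto"`` dispatches on per-group Shapiro-Wilk normality;
    ``rule`` may instead force ``"t"``, ``"mannwhitney"``, ``"wilcoxon"``,
    ``"anova_tukey"`` or ``"kruskal"``.  The default two-sample t-test is
    Welch's (``equal_var=True`` gives the pooled-variance form).
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    if design == "paired":
        if len(groups) != 2:
            raise ValueError("paired design takes exactly two groups")
        if len(groups[0]) != len(groups[1]):
            raise ValueError("paired design requires equal group lengths")
    summaries = _summaries(groups)

    if rule == "auto":
        normal = _all_normal(groups)
        if design == "multi" and len(groups) > 2:
            rule = "anova_tukey" if normal else "kruskal"
        elif design == "paired":
            rule = "t" if normal else "wilcoxon"
        else:
            rule = "t" if normal else "mannwhitney"

    paired = design == "paired"
    if rule == "t":
        if paired:
            res = sps.ttest_rel(groups[0], groups[1])
            name = "paired t"
        else:
            res = sps.ttest_ind(groups[0], groups[1], equal_var=equal_var)
            name = "t (pooled)" if equal_var else "t (Welch)"
        return ComparisonResult(name, float(res.statistic), float(res.pvalue),
                                summaries, paired)
    if rule == "mannwhitney":
        res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return ComparisonResult("Mann-Whitney U", float(res.statistic),
                                float(res.pvalue), summaries)
    if rule == "wilcoxon":
        if np.allclose(groups[0], groups[1]):
            return ComparisonResult("Wilcoxon signed-rank", 0.0, 1.0, summaries, True)
        res = sps.wilcoxon(groups[0], groups[1])
        return ComparisonResult("Wilcoxon signed-rank", float(res.statistic),
                                float(res.pvalue), summaries, True)
    if rule == "anova_tukey":
        res = sps.f_oneway(*groups)
        tukey = sps.tukey_hsd(*groups)
        pairwise = {
            (i, j): float(tukey.pvalue[i, j])
            for i in range(len(groups)) for j in range(i + 1, len(groups))
        }
        return ComparisonResult("ANOVA + Tukey HSD", float(res.statistic),
                                float(res.pvalue), summaries,
                                correction="tukey", pairwise=pairwise)
    if rule == "kruskal":
        res = sps.kruskal(*groups)
        return ComparisonResult("Kruskal-Wallis", float(res.statistic),
                                float(res.pvalue), summaries)
    raise ValueError(f"unknown rule {rule!r}")


def ks_compare(sample_a: np.ndarray, sample_b: np.ndarray) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov test (sup of ECDF difference)."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 observations per sample")
    res = sps.ks_2samp(a, b, method="asymp")
    return ComparisonResult("Kolmogorov-Smirnov", float(res.statistic),
                            float(res.pvalue), _summaries([a, b]))


def bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni-adjusted p-values (never below the raw p; capped at 1)."""
    m = len(p_values)
    return [min(1.0, max(p, p * m)) for p in p_values]
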