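"""Group-comparison statistics for cohort validation tables.

One-way ANOVA (from raw data or from published per-group summary moments),
pairwise pooled-variance contrasts at a Bonferroni-corrected α, chi-square
independence tests for categorical mixes, Pearson correlations with the
conventional strength bands (|r| ≥ 0.4 moderate, ≥ 0.7 strong), and
Steiger's Z for comparing dependent correlations that share one variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "CorrelationReport",
    "anova_oneway",
    "anova_from_summary",
    "chi_square_independence",
    "pearson_correlations",
    "strength_label",
    "steiger_dependent_correlation_test",
    "BONFERRONI_ALPHA",
]

#: Bonferroni-corrected per-contrast significance level for three pairwise
#: comparisons (0.05 / 3, as conventionally rounded in screening studies).
BONFERRONI_ALPHA = 0.017


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA with pairwise post-hoc contrasts.

    ``pairwise`` maps each group pair to its pooled-variance t statistic,
    two-sided p-value and significance flag at the corrected α.
    """

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: Mapping[tuple[str, str], dict] = field(default_factory=dict)
    alpha: float = BONFERRONI_ALPHA


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation matrix with strength bands and p-values."""

    variables: tuple[str, ...]
    r_matrix: np.ndarray
    p_values: np.ndarray
    strength_labels: Mapping[tuple[str, str], str]


def _pooled_t_from_summary(n1, m1, s1, n2, m2, s2) -> tuple[float, float]:
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0:
        raise ValueError("pooled variance is zero; t statistic undefined")
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def anova_oneway(values, group_labels, alpha: float = BONFERRONI_ALPHA) -> AnovaResult:
    """Classical one-way ANOVA with pooled-variance pairwise t-tests.

    Groups need at least two observations each.  When every observation is
    identical the F ratio is 0/0 and a ``ValueError`` is raised rather than
    returning a silent NaN.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    labels = list(dict.fromkeys(g.tolist()))  # keep first-appearance order
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    groups = {lab: x[g == lab] for lab in labels}
    for lab, xs in groups.items():
        if xs.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")
    ns = np.array([groups[lab].size for lab in labels])
    means = np.array([groups[lab].mean() for lab in labels])
    grand = x.mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((groups[lab] - groups[lab].mean()) ** 2).sum() for lab in labels))
    df_b, df_w = len(labels) - 1, x.size - len(labels)
    if ss_within == 0 and ss_between == 0:
        raise ValueError("all observations identical; F = 0/0 is undefined")
    if ss_within == 0:
        raise ValueError("zero within-group variance; F is unbounded")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    pairwise = {}
    for a, b in combinations(labels, 2):
        t, pt = _pooled_t_from_summary(
            groups[a].size, groups[a].mean(), groups[a].std(ddof=1),
            groups[b].size, groups[b].mean(), groups[b].std(ddof=1),
        )
        pairwise[(a, b)] = {"t": t, "p": pt, "significant": pt < alpha}
    return AnovaResult(float(f), df_b, df_w, p, pairwise, alpha)


def anova_from_summary(
    ns: Sequence[int],
    means: Sequence[float],
    sds: Sequence[float],
    labels: Sequence[str] | None = None,
    alpha: float = BONFERRONI_ALPHA,
) -> AnovaResult:
    """One-way ANOVA recomputed from per-group (n, mean, SD) summaries.

    SDs are taken as sample SDs (n−1 denominator).  Identical to
    :func:`anova_oneway` on any raw data possessing exactly these moments,
    which is how published F statistics are reproduced from summary tables.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (ns.shape == means.shape == sds.shape) or ns.size < 2:
        raise ValueError("ns, means and sds must be equal-length with >= 2 groups")
    if np.any(ns < 2) or np.any(sds < 0):
        raise ValueError("each group needs n >= 2 and sd >= 0")
    if labels is None:
        labels = [f"G{i + 1}" for i in range(ns.size)]
    N = ns.sum()
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_b, df_w = ns.size - 1, int(N - ns.size)
    if ss_within == 0:
        raise ValueError("all SDs zero; F is undefined")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    pairwise = {}
    for i, j in combinations(range(ns.size), 2):
        t, pt = _pooled_t_from_summary(ns[i], means[i], sds[i], ns[j], means[j], sds[j])
        pairwise[(labels[i], labels[j])] = {"t": t, "p": pt, "significant": pt < alpha}
    return AnovaResult(float(f), int(df_b), df_w, p, pairwise, alpha)


def chi_square_independence(contingency_table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Expected counts come from the table margins; df = (rows−1)(cols−1).
    """
    table = np.asarray(contingency_table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def strength_label(r: float) -> str:
    """Conventional correlation strength band by absolute value."""
    a = abs(r)
    if a >= 0.7:
        return "strong"
    if a >= 0.4:
        return "moderate"
    return "weak"


def pearson_correlations(
    score_table: pd.DataFrame,
    variable_pairs: Sequence[tuple[str, str]] | None = None,
    variables: Sequence[str] | None = None,
) -> CorrelationReport:
    """Pearson correlations with strength bands over selected variable pairs.

    Either an explicit pair list or a variable list (all pairs) may be given;
    by default every numeric column is used.  Each pair needs at least three
    complete observations and nonzero variance on both sides.
    """
    if variables is None:
        if variable_pairs is not None:
            variables = list(dict.fromkeys([v for pair in variable_pairs for v in pair]))
        else:
            variables = list(score_table.select_dtypes("number").columns)
    variables = tuple(variables)
    if variable_pairs is None:
        variable_pairs = list(combinations(variables, 2))
    k = len(variables)
    pos = {v: i for i, v in enumerate(variables)}
    r_matrix = np.eye(k)
    p_values = np.zeros((k, k))
    labels: dict[tuple[str, str], str] = {}
    for a, b in variable_pairs:
        sub = score_table[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"pair ({a}, {b}) has fewer than 3 complete observations")
        if sub[a].std(ddof=1) == 0 or sub[b].std(ddof=1) == 0:
            raise ValueError(f"pair ({a}, {b}) has a zero-variance variable")
        res = stats.pearsonr(sub[a], sub[b])
        i, j = pos[a], pos[b]
        r_matrix[i, j] = r_matrix[j, i] = res.statistic
        p_values[i, j] = p_values[j, i] = res.pvalue
        labels[(a, b)] = strength_label(res.statistic)
    return CorrelationReport(variables, r_matrix, p_values, labels)


def steiger_dependent_correlation_test(
    r_jk: float, r_jh: float, r_kh: float, n: int
) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable j.

    Tests r(j,k) = r(j,h) given the correlation r(k,h) between the two
    non-shared variables, with the covariance term evaluated at the
    back-transformed average of the two compared correlations.  Returns
    (Z, two-sided p).
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name}={r} must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("Steiger's test needs n > 3")
    z1, z2 = np.arctanh(r_jk), np.arctanh(r_jh)
    rbar = np.tanh(0.5 * (z1 + z2))
    rb2 = rbar**2
    cov = (r_kh * (1 - 2 * rb2) - 0.5 * rb2 * (1 - 2 * rb2 - r_kh**2)) / (1 - rb2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - cov)))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
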